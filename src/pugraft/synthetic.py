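"""Synthetic uniaxial tensile curves with the structure of elastomer data.

No public tensile dataset accompanies the compliance analysis, so the fitting
and simulation stages are exercised on generated curves: forward evaluation
of the Mooney-Rivlin uniaxial stress on a uniform stretch grid, converted to
the measured (engineering) scale, with

* additive Gaussian noise on engineering stress — the instrument measures
  force over original area, so that is where measurement error lives;
* multiplicative lognormal jitter on the coefficient triple per replicate —
  specimen-to-specimen variability that cannot flip coefficient signs;
* an optional hydration-softening factor scaling all three coefficients,
  the minimal model of water acting as a plasticizer (softer, shorter
  curves are obtained by also lowering ``lambda_max``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .datamodel import MooneyRivlinParams, UniaxialCurve
from .hyperelastic import uniaxial_stress

__all__ = ["SyntheticSpec", "generate_curve", "generate_replicates"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one replicate set of synthetic tensile curves.

    ``noise_sd`` is the additive Gaussian sd on engineering stress in MPa;
    ``replicate_jitter_cv`` the coefficient of variation of the per-replicate
    lognormal multiplier applied independently to each coefficient;
    ``hydration_softening_factor`` in (0, 1] scales all coefficients (1 means
    non-hydrated).
    """

    true_params: MooneyRivlinParams
    lambda_max: float = 2.5
    n_points: int = 200
    n_replicates: int = 5
    noise_sd: float = 0.02
    replicate_jitter_cv: float = 0.05
    hydration_softening_factor: float = 1.0
    seed: int = 0
    composition_label: str = "synthetic"
    hydration_state: str = "non_hydrated"

    def __post_init__(self) -> None:
        if not self.lambda_max > 1:
            raise ValueError(f"lambda_max must be > 1, got {self.lambda_max}")
        if self.n_points < 10:
            raise ValueError(f"n_points must be >= 10, got {self.n_points}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 < self.hydration_softening_factor <= 1:
            raise ValueError(
                "hydration_softening_factor must lie in (0, 1], got "
                f"{self.hydration_softening_factor}"
            )
        if self.replicate_jitter_cv < 0:
            raise ValueError(
                f"replicate_jitter_cv must be >= 0, got {self.replicate_jitter_cv}"
            )
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")


def _effective_params(spec: SyntheticSpec) -> MooneyRivlinParams:
    if spec.hydration_softening_factor == 1.0:
        return spec.true_params
    return spec.true_params.scaled(spec.hydration_softening_factor)


def _check_nonnegative_stress(params: MooneyRivlinParams, lambda_max: float) -> None:
    # sample finer than any plausible output grid so dips between nodes are caught
    lam = np.linspace(1.0, lambda_max, 1024)
    sig = uniaxial_stress(lam, params)
    if np.min(sig) < -1e-12:
        lam_bad = lam[int(np.argmin(sig))]
        raise ValueError(
            f"model stress is negative ({np.min(sig):.3g} MPa at stretch "
            f"{lam_bad:.3f}); choose coefficients with a non-negative response "
            f"over [1, {lambda_max}]"
        )


def generate_curve(
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    params: Optional[MooneyRivlinParams] = None,
    specimen_id: str = "synthetic-0",
) -> UniaxialCurve:
    """One synthetic tensile curve on a uniform stretch grid [1, lambda_max].

    Engineering stress is sigma1(lambda)/lambda; noise is added on the
    engineering scale and clipped at zero; the first sample is exactly
    (strain 0, stress 0) — the instrument's tare point.

    ``params`` overrides the (softening-scaled) spec coefficients; used by
    :func:`generate_replicates` to inject per-replicate jitter.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = params if params is not None else _effective_params(spec)
    _check_nonnegative_stress(p, spec.lambda_max)

    lam = np.linspace(1.0, spec.lambda_max, spec.n_points)
    sigma_true = uniaxial_stress(lam, p)
    sigma_eng = sigma_true / lam
    if spec.noise_sd > 0:
        sigma_eng = sigma_eng + rng.normal(0.0, spec.noise_sd, size=lam.size)
        sigma_eng = np.clip(sigma_eng, 0.0, None)
    strain = lam - 1.0
    strain[0] = 0.0
    sigma_eng[0] = 0.0
    return UniaxialCurve(
        specimen_id=specimen_id,
        composition_label=spec.composition_label,
        hydration_state=spec.hydration_state,
        strain_eng=strain,
        stress_eng=sigma_eng,
    )


def generate_replicates(spec: SyntheticSpec) -> List[UniaxialCurve]:
    """A replicate set with independent lognormal coefficient jitter.

    Each replicate's coefficients are the spec's (softening-scaled) values
    multiplied by independent lognormal draws with unit mean and coefficient
    of variation ``replicate_jitter_cv``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    base = _effective_params(spec)
    cv = spec.replicate_jitter_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        mu = -0.5 * sigma**2  # unit-mean lognormal
    curves = []
    for i in range(spec.n_replicates):
        if cv > 0:
            mult = rng.lognormal(mean=mu, sigma=sigma, size=3)
            p = MooneyRivlinParams(
                c10=base.c10 * mult[0],
                c01=base.c01 * mult[1],
                c11=base.c11 * mult[2],
                temperature=base.temperature,
            )
        else:
            p = base
        curves.append(
            generate_curve(
                spec,
                rng=rng,
                params=p,
                specimen_id=f"{spec.composition_label}-r{i + 1}",
            )
        )
    return curves
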