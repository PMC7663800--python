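"""Pulsatile-pressure simulation of a cylindrical elastomer graft.

The pressure is a sinusoid around the mean arterial pressure,
P(t) = Pm (1 + eps sin(2 pi f t)) with eps = Ps / Pm.  Thick-wall theory
gives the circumferential (hoop) wall stress

    sigma_theta = P * (r0^2 / (r0+h)^2) * (1 + (r0+h)^2 / r0^2)
                = P * (1 + r0^2 / (r0+h)^2),

which depends on geometry only through the thickness-to-radius ratio h/r0.
The hoop stress is mapped to a circumferential stretch by inverting the
uniaxial Mooney-Rivlin stress, the radius history is r(t) = r0 * lambda(t),
and compliance is the forward-difference distensibility

    C_i = (r_{i+1} - r_i) / (r_i (P_{i+1} - P_i))     [1/mmHg].

The wall model is purely elastic (rate-independent), so the response at any
frequency is the same loop traversed at a different speed, and compliance
depends on geometry only through h/r0 — both properties are exercised by the
test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .datamodel import (
    ComplianceSeries,
    GraftGeometry,
    MooneyRivlinParams,
    PressureWaveform,
    StabilityError,
    StressRangeError,
)
from .hyperelastic import uniaxial_stress

__all__ = [
    "MMHG_TO_MPA",
    "SweepResult",
    "mean_pressure",
    "physiological_waveform",
    "pressure_at",
    "hoop_stress",
    "invert_stretch",
    "simulate",
    "sweep",
]

#: 1 mmHg in MPa (133.322 Pa).
MMHG_TO_MPA = 1.33322e-4

#: Default stretch-solve bracket upper bound; well below tensile-fit ranges.
DEFAULT_LAMBDA_HI = 3.0

#: |dP| (mmHg) below which the forward-difference compliance is a gap.
DEFAULT_DP_GAP = 1e-6


@dataclass
class SweepResult:
    """Compliance series over an (omega, r0, h) grid for one material."""

    material_label: str
    series: Dict[Tuple[float, float, float], ComplianceSeries]
    summary: "object"  # pandas.DataFrame: one row per grid cell
    failures: Dict[Tuple[float, float, float], str] = field(default_factory=dict)


def mean_pressure(p_max: float, p_min: float) -> float:
    """Mean arterial pressure: one third systolic plus two thirds diastolic.

    Diastole occupies roughly two thirds of the cardiac cycle, hence the
    unequal weighting.
    """
    if p_max < p_min:
        raise ValueError(f"p_max ({p_max}) must be >= p_min ({p_min})")
    return p_max / 3.0 + 2.0 * p_min / 3.0


def physiological_waveform(
    p_max: float = 180.0,
    p_min: float = 40.0,
    amplitude_ps: float = 10.0,
    omega: float = 1.0,
) -> PressureWaveform:
    """Waveform built from systolic/diastolic extremes; defaults are the
    study conditions (180/40 mmHg, 10 mmHg sinusoid amplitude, 1 Hz)."""
    pm = mean_pressure(p_max, p_min)
    return PressureWaveform(
        p_max=p_max,
        p_min=p_min,
        p_mean=pm,
        amplitude_ps=amplitude_ps,
        epsilon=amplitude_ps / pm,
        omega=omega,
    )


def pressure_at(t, wf: PressureWaveform):
    """P(t) = Pm (1 + eps sin(2 pi f t)) in mmHg; vectorised over ``t``.

    ``wf.omega`` is an ordinary frequency in Hz, so the sinusoid argument
    carries the 2*pi factor and one pressure cycle spans 1/omega seconds.
    """
    t = np.asarray(t, dtype=float)
    out = wf.p_mean * (1.0 + wf.epsilon * np.sin(2.0 * np.pi * wf.omega * t))
    return float(out) if out.ndim == 0 else out


def hoop_stress(pressure_mmhg, geom: GraftGeometry):
    """Thick-wall circumferential stress in MPa for a pressure in mmHg.

    Homogeneous of degree zero in (r0, h): scaling the geometry uniformly
    leaves the stress unchanged.
    """
    p = np.asarray(pressure_mmhg, dtype=float)
    ratio2 = geom.inner_radius_r0**2 / (geom.inner_radius_r0 + geom.thickness_h) ** 2
    out = p * MMHG_TO_MPA * (1.0 + ratio2)
    return float(out) if out.ndim == 0 else out


def _check_monotone(
    params: MooneyRivlinParams,
    lambda_hi: float,
    material: Optional[str],
    n_samples: int = 512,
) -> None:
    lam = np.linspace(1.0, lambda_hi, n_samples)
    sig = uniaxial_stress(lam, params)
    if np.any(np.diff(sig) <= 0):
        who = material or "material"
        raise StabilityError(
            f"{who}: uniaxial stress is not strictly increasing on "
            f"[1, {lambda_hi}]; the stretch inversion is ill-posed"
        )


def invert_stretch(
    target_stress: float,
    params: MooneyRivlinParams,
    lambda_hi: float = DEFAULT_LAMBDA_HI,
    material: Optional[str] = None,
    _skip_checks: bool = False,
) -> float:
    """Stretch at which the uniaxial Cauchy stress equals ``target_stress`` (MPa).

    Bracketed root solve on [1, lambda_hi]; monotonicity of the stress on the
    bracket is verified by sampling first.  Returns exactly 1.0 for a zero
    target (sigma1(1) = 0 analytically).

    Raises
    ------
    StabilityError
        Non-monotone stress on the bracket (names the material if given).
    StressRangeError
        Target above sigma1(lambda_hi).
    """
    if target_stress < 0:
        raise ValueError(f"target stress must be >= 0, got {target_stress}")
    if target_stress == 0.0:
        return 1.0
    if not _skip_checks:
        _check_monotone(params, lambda_hi, material)
    hi_stress = uniaxial_stress(lambda_hi, params)
    if target_stress > hi_stress:
        raise StressRangeError(
            f"target stress {target_stress:.6g} MPa exceeds sigma1({lambda_hi}) "
            f"= {hi_stress:.6g} MPa"
        )
    return float(
        brentq(
            lambda lam: uniaxial_stress(lam, params) - target_stress,
            1.0,
            lambda_hi,
            xtol=1e-14,
            rtol=8.9e-16,
        )
    )


def simulate(
    params: MooneyRivlinParams,
    wf: PressureWaveform,
    geom: GraftGeometry,
    n_cycles: int = 3,
    samples_per_cycle: int = 256,
    lambda_hi: float = DEFAULT_LAMBDA_HI,
    dp_gap: float = DEFAULT_DP_GAP,
    material: Optional[str] = None,
) -> ComplianceSeries:
    """Full pressure -> hoop stress -> stretch -> radius -> compliance chain.

    The time grid is uniform with ``samples_per_cycle`` intervals per pressure
    cycle over ``n_cycles`` cycles (plus the closing endpoint).  The sinusoid
    phase is evaluated modulo one cycle so samples at the same phase in
    different cycles are bit-identical — the elastic model has no transient,
    and this keeps the compliance series exactly periodic instead of periodic
    only to the round-off of large sine arguments.

    Compliance entries where |dP| < ``dp_gap`` (pressure turning points, where
    the forward difference is 0/0) are NaN gaps, not zeros; summary statistics
    downstream ignore them.
    """
    if n_cycles < 1 or samples_per_cycle < 16:
        raise ValueError("need n_cycles >= 1 and samples_per_cycle >= 16")
    n = n_cycles * samples_per_cycle + 1
    idx = np.arange(n)
    t = idx / (samples_per_cycle * wf.omega)
    phase = 2.0 * np.pi * (idx % samples_per_cycle) / samples_per_cycle
    pressure = wf.p_mean * (1.0 + wf.epsilon * np.sin(phase))
    stress = hoop_stress(pressure, geom)

    _check_monotone(params, lambda_hi, material)
    if stress.max() > uniaxial_stress(lambda_hi, params):
        raise StressRangeError(
            f"peak hoop stress {stress.max():.6g} MPa exceeds the invertible "
            f"range of {material or 'the material'}"
        )

    # one root solve per distinct phase; cycles reuse the same stretches
    lam = np.empty(n)
    cache: Dict[int, float] = {}
    for i in range(n):
        key = int(idx[i] % samples_per_cycle)
        if key not in cache:
            cache[key] = invert_stretch(
                float(stress[i]), params, lambda_hi, material, _skip_checks=True
            )
        lam[i] = cache[key]

    radius = geom.inner_radius_r0 * lam
    dp = np.diff(pressure)
    compliance = np.full(n - 1, np.nan)
    ok = np.abs(dp) >= dp_gap
    compliance[ok] = (radius[1:] - radius[:-1])[ok] / (radius[:-1][ok] * dp[ok])
    return ComplianceSeries(
        time=t,
        pressure=pressure,
        hoop_stress=stress,
        stretch=lam,
        radius=radius,
        compliance=compliance,
    )


def summarize(
    series: ComplianceSeries, samples_per_cycle: int
) -> Tuple[float, float, float]:
    """(min, max, mean) compliance ignoring gaps and the first cycle.

    The first cycle is discarded as a guard (the elastic model has no
    transient, so this is conservative, not load-bearing).
    """
    c = series.compliance[samples_per_cycle:]
    if c.size == 0:
        c = series.compliance
    c = c[np.isfinite(c)]
    return float(np.min(c)), float(np.max(c)), float(np.mean(c))


def sweep(
    params: MooneyRivlinParams,
    wf: PressureWaveform,
    omega_grid: Sequence[float],
    r0_grid: Sequence[float],
    h_grid: Sequence[float],
    n_cycles: int = 3,
    samples_per_cycle: int = 256,
    lambda_hi: float = DEFAULT_LAMBDA_HI,
    material_label: str = "material",
) -> SweepResult:
    """Simulate every (omega, r0, h) grid cell; collect per-cell failures.

    The summary table reports min/max/mean compliance per cell in 1/mmHg and
    also scaled by 1e4 (the conventional reporting scale for arterial
    compliance).
    """
    import pandas as pd

    if not (len(omega_grid) and len(r0_grid) and len(h_grid)):
        raise ValueError("all sweep grids must be non-empty")
    series: Dict[Tuple[float, float, float], ComplianceSeries] = {}
    failures: Dict[Tuple[float, float, float], str] = {}
    rows: List[dict] = []
    for omega in omega_grid:
        wf_cell = PressureWaveform(
            p_max=wf.p_max,
            p_min=wf.p_min,
            p_mean=wf.p_mean,
            amplitude_ps=wf.amplitude_ps,
            epsilon=wf.epsilon,
            omega=omega,
        )
        for r0 in r0_grid:
            for h in h_grid:
                key = (omega, r0, h)
                try:
                    cs = simulate(
                        params,
                        wf_cell,
                        GraftGeometry(r0, h),
                        n_cycles=n_cycles,
                        samples_per_cycle=samples_per_cycle,
                        lambda_hi=lambda_hi,
                        material=material_label,
                    )
                except Exception as exc:  # collected, sweep continues
                    failures[key] = f"{type(exc).__name__}: {exc}"
                    continue
                series[key] = cs
                cmin, cmax, cmean = summarize(cs, samples_per_cycle)
                rows.append(
                    {
                        "material": material_label,
                        "omega_hz": omega,
                        "r0_mm": r0,
                        "h_mm": h,
                        "compliance_min_per_mmHg": cmin,
                        "compliance_max_per_mmHg": cmax,
                        "compliance_mean_per_mmHg": cmean,
                        "compliance_mean_per_mmHg_x1e4": cmean * 1e4,
                    }
                )
    return SweepResult(
        material_label=material_label,
        series=series,
        summary=pd.DataFrame(rows),
        failures=failures,
    )
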