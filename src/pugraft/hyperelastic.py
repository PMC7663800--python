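"""Three-parameter Mooney-Rivlin model for incompressible uniaxial extension.

The strain-energy density retains the first-order and cross terms of the
Mooney-Rivlin polynomial,

    W = C10 (I1 - 3) + C01 (I2 - 3) + C11 (I1 - 3)(I2 - 3),

with the invariants built from the principal stretches of an incompressible
uniaxial state (lambda, lambda^-1/2, lambda^-1/2), so I3 = 1 identically.
Eliminating the hydrostatic pressure with sigma2 = sigma3 = 0 gives the
uniaxial Cauchy stress

    sigma1(lambda) = 2 C10 (lambda^2 - 1/lambda)
                   + 2 C01 (lambda - 1/lambda^2)
                   + 6 C11 (lambda^3 - lambda^2 - lambda
                            + 1/lambda + 1/lambda^2 - 1/lambda^3),

which is linear in (C10, C01, C11).  Coefficient estimation from a true
stress-stretch curve is therefore an ordinary linear least-squares problem
with an exact global optimum; an optional nonlinear refinement path exists
purely as a cross-check.

Rubber-elasticity theory links C10 to the density of effective network
chains, v = |C10| / (R T), reported here in kmol/m^3 with
R = 8314 J kmol^-1 K^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datamodel import FitError, FitResult, MooneyRivlinParams

__all__ = [
    "GAS_CONSTANT",
    "StretchState",
    "uniaxial_state",
    "energy",
    "stress_basis",
    "uniaxial_stress",
    "fit",
    "concordance_ccc",
    "crosslink_density",
    "initial_slope",
]

#: Universal gas constant in J kmol^-1 K^-1 (so that v lands in kmol/m^3).
GAS_CONSTANT = 8314.0


@dataclass(frozen=True)
class StretchState:
    """Principal stretches and strain invariants of a deformation state."""

    lambda1: float
    lambda2: float
    lambda3: float
    i1: float
    i2: float
    i3: float


def uniaxial_state(stretch: float) -> StretchState:
    """Incompressible uniaxial state at axial stretch ``lambda``.

    The lateral stretches are ``lambda**-0.5`` so the third invariant is 1
    (volume conservation).

    Raises
    ------
    ValueError
        If ``stretch`` is not strictly positive.
    """
    if not stretch > 0:
        raise ValueError(f"stretch must be > 0, got {stretch}")
    lam = float(stretch)
    lat = lam ** -0.5
    i1 = lam**2 + 2.0 / lam
    i2 = 1.0 / lam**2 + 2.0 * lam
    i3 = lam**2 * lat**4
    return StretchState(lam, lat, lat, i1, i2, i3)


def energy(state: StretchState, params: MooneyRivlinParams) -> float:
    """Strain-energy density W (MPa) at a deformation state."""
    a = state.i1 - 3.0
    b = state.i2 - 3.0
    return params.c10 * a + params.c01 * b + params.c11 * a * b


def stress_basis(stretch):
    """The three basis functions of the uniaxial Cauchy stress.

    Returns ``(b10, b01, b11)`` with ``sigma1 = C10*b10 + C01*b01 + C11*b11``.
    Vectorised over ``stretch``.
    """
    lam = np.asarray(stretch, dtype=float)
    inv = 1.0 / lam
    b10 = 2.0 * (lam**2 - inv)
    b01 = 2.0 * (lam - inv**2)
    b11 = 6.0 * (lam**3 - lam**2 - lam + inv + inv**2 - inv**3)
    return b10, b01, b11


def uniaxial_stress(stretch, params: MooneyRivlinParams):
    """Uniaxial Cauchy stress sigma1 (MPa) at the given stretch(es).

    Identically zero at lambda = 1 for any coefficient triple: every basis
    bracket vanishes in the undeformed state.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be > 0")
    b10, b01, b11 = stress_basis(lam)
    out = params.c10 * b10 + params.c01 * b01 + params.c11 * b11
    if np.isscalar(stretch) or np.ndim(stretch) == 0:
        return float(out)
    return out


def initial_slope(params: MooneyRivlinParams) -> float:
    """d(sigma1)/d(lambda) at lambda = 1, analytically 6*(C10 + C01) MPa.

    The C11 bracket has zero slope at the undeformed state, so the small-strain
    stiffness is controlled by the first two coefficients alone.
    """
    return 6.0 * (params.c10 + params.c01)


def concordance_ccc(observed, predicted) -> float:
    """Lin's concordance correlation coefficient between two series.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), with population
    (1/n) moments as in Lin's original estimator.  Measures agreement with the
    45-degree identity line, not just correlation; lies in [-1, 1].
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both series are constant and equal")
    sxy = np.mean((x - mx) * (y - my))
    return float(2.0 * sxy / denom)


def crosslink_density(params: MooneyRivlinParams, temperature: float | None = None) -> float:
    """Effective network-chain density v = |C10| / (R T) in kmol/m^3.

    C10 is converted from MPa to Pa; R = 8314 J kmol^-1 K^-1.  The magnitude
    of C10 is used so that coefficient sets with a negative fitted C10 (common
    for this model) still yield a physically non-negative density.
    """
    T = params.temperature if temperature is None else temperature
    if not T > 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return abs(params.c10) * 1e6 / (GAS_CONSTANT * T)


def fit(
    stretch,
    stress_true,
    temperature: float = 310.15,
    method: str = "linear",
) -> FitResult:
    """Estimate (C10, C01, C11) from a true stress-stretch curve.

    The model is linear in its coefficients, so ``method="linear"`` solves the
    least-squares problem exactly via SVD (:func:`numpy.linalg.lstsq`).
    ``method="nls"`` runs a Levenberg-Marquardt refinement from the linear
    solution and exists only as a consistency cross-check; the two agree to
    well below 1e-8.

    Parameters
    ----------
    stretch, stress_true
        Equal-length series; stretch > 0, at least 3 points, true stress
        in MPa.
    temperature
        Kelvin; used for the crosslink density and stored on the params.

    Raises
    ------
    FitError
        Rank-deficient design (e.g. all stretches equal) or fewer than
        3 points.
    CurveDataError-like ValueError
        NaNs in the input.
    """
    lam = np.asarray(stretch, dtype=float)
    sig = np.asarray(stress_true, dtype=float)
    if lam.shape != sig.shape or lam.ndim != 1:
        raise ValueError("stretch and stress must be equal-length 1-d series")
    if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(sig))):
        raise FitError("input contains non-finite values")
    if lam.size < 3:
        raise FitError(f"need at least 3 points, got {lam.size}")
    if np.any(lam <= 0):
        raise ValueError("stretch values must be > 0")

    design = np.column_stack(stress_basis(lam))
    rank = np.linalg.matrix_rank(design)
    if rank < 3:
        raise FitError(
            f"rank-deficient design (rank {rank} < 3); "
            "need at least 3 distinct stretches above 1"
        )
    coef, *_ = np.linalg.lstsq(design, sig, rcond=None)

    if method == "nls":
        def residual(c):
            return design @ c - sig

        sol = optimize.least_squares(residual, coef, method="lm")
        coef = sol.x
    elif method != "linear":
        raise ValueError(f"unknown method {method!r}")

    params = MooneyRivlinParams(
        c10=float(coef[0]), c01=float(coef[1]), c11=float(coef[2]),
        temperature=temperature,
    )
    predicted = design @ coef
    resid = sig - predicted
    rmse = float(np.sqrt(np.mean(resid**2)))
    ccc = concordance_ccc(sig, predicted)
    return FitResult(
        params=params,
        rmse=rmse,
        ccc=min(ccc, 1.0),
        crosslink_density=crosslink_density(params),
        n_points=int(lam.size),
        initial_slope=initial_slope(params),
    )
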