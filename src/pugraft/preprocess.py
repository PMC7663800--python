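"""Engineering-to-true conversion, replicate averaging, and dynamic moduli.

For an incompressible uniaxial specimen the current cross-section shrinks by
the stretch factor, so true (Cauchy) stress relates to engineering stress as
``sigma_true = lambda * sigma_eng`` with ``lambda = 1 + eps_eng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .datamodel import CurveDataError, UniaxialCurve

__all__ = ["AveragedCurve", "DynamicPoint", "to_true", "average_curves", "dynamic_moduli"]


@dataclass
class AveragedCurve:
    """Replicate-averaged true stress on a common stretch grid."""

    composition_label: str
    hydration_state: str
    stretch_grid: np.ndarray
    stress_true_mean: np.ndarray
    stress_true_sd: np.ndarray
    n_replicates: int


@dataclass(frozen=True)
class DynamicPoint:
    """One oscillatory measurement decomposed into storage and loss moduli.

    E' = (sigma/eps) cos(delta), E'' = (sigma/eps) sin(delta); delta is the
    phase lag between stress and strain in radians.
    """

    stress_amplitude: float
    strain_amplitude: float
    phase_angle_delta: float
    storage_modulus: float
    loss_modulus: float


def to_true(curve: UniaxialCurve) -> UniaxialCurve:
    """Fill the derived stretch and true-stress fields of a curve.

    Returns a new curve; the input is not modified.
    """
    stretch = 1.0 + curve.strain_eng
    stress_true = stretch * curve.stress_eng
    return replace(curve, stretch=stretch, stress_true=stress_true)


def average_curves(curves: Sequence[UniaxialCurve], n_grid: int = 200) -> AveragedCurve:
    """Pointwise mean and sd of replicate true-stress curves on a shared grid.

    The grid is uniform on [1, min over curves of max stretch] — truncation to
    the shortest replicate, since elastomer replicates break at different
    elongations — and each curve is linearly interpolated onto it.  The sd is
    the sample standard deviation across replicates (0 for a single curve).

    Raises
    ------
    ValueError
        Empty replicate list, or mixed composition/hydration labels.
    CurveDataError
        Overlapping stretch range shorter than two grid points.
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve to average")
    label = curves[0].composition_label
    state = curves[0].hydration_state
    for c in curves:
        if c.composition_label != label or c.hydration_state != state:
            raise ValueError("all replicates must share composition and hydration state")
    if n_grid < 2:
        raise ValueError(f"n_grid must be >= 2, got {n_grid}")

    derived = [c if c.stretch is not None else to_true(c) for c in curves]
    hi = min(float(c.stretch[-1]) for c in derived)
    if hi <= 1.0:
        raise CurveDataError(
            f"overlapping stretch range [1, {hi}] is degenerate; cannot build a grid"
        )
    grid = np.linspace(1.0, hi, n_grid)
    stack = np.vstack([np.interp(grid, c.stretch, c.stress_true) for c in derived])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(derived) > 1 else np.zeros_like(mean)
    return AveragedCurve(
        composition_label=label,
        hydration_state=state,
        stretch_grid=grid,
        stress_true_mean=mean,
        stress_true_sd=sd,
        n_replicates=len(derived),
    )


def dynamic_moduli(
    stress_amplitude: float, strain_amplitude: float, delta: float
) -> DynamicPoint:
    """Storage and loss moduli from an oscillation amplitude pair and phase lag.

    Parameters
    ----------
    stress_amplitude : MPa
    strain_amplitude : dimensionless, > 0
    delta : radians in [0, pi/2]
    """
    if strain_amplitude <= 0:
        raise ValueError(f"strain amplitude must be > 0, got {strain_amplitude}")
    if not 0.0 <= delta <= math.pi / 2:
        raise ValueError(f"phase angle must lie in [0, pi/2], got {delta}")
    ratio = stress_amplitude / strain_amplitude
    return DynamicPoint(
        stress_amplitude=stress_amplitude,
        strain_amplitude=strain_amplitude,
        phase_angle_delta=delta,
        storage_modulus=ratio * math.cos(delta),
        loss_modulus=ratio * math.sin(delta),
    )
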