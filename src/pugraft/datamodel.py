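"""Shared domain types for polyurethane vascular-graft mechanics.

Conventions used throughout the package:

* stresses and moduli are carried internally in MPa;
* pressures are accepted and reported in mmHg and converted to MPa only
  where a pressure meets a stress (``graftsim.MMHG_TO_MPA``);
* strain is dimensionless (fraction, not percent);
* stretch ``lambda = 1 + engineering strain``;
* temperatures are in kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "PUGraftError",
    "CurveFormatError",
    "CurveDataError",
    "ConfigError",
    "FitError",
    "StabilityError",
    "StressRangeError",
    "HYDRATION_STATES",
    "UniaxialCurve",
    "MooneyRivlinParams",
    "FitResult",
    "PressureWaveform",
    "GraftGeometry",
    "ComplianceSeries",
]


class PUGraftError(Exception):
    """Base class for all package errors."""


class CurveFormatError(PUGraftError):
    """Raised when a curve file is structurally unreadable (missing columns)."""


class CurveDataError(PUGraftError):
    """Raised when curve data violate an invariant (too short, non-monotone)."""


class ConfigError(PUGraftError):
    """Raised when a run configuration fails validation."""


class FitError(PUGraftError):
    """Raised when the least-squares design is rank deficient or the data are unusable."""


class StabilityError(PUGraftError):
    """Raised when the stress-stretch relation is non-monotone on the solve bracket."""


class StressRangeError(PUGraftError):
    """Raised when a target stress lies outside the invertible bracket."""


HYDRATION_STATES = ("non_hydrated", "hydrated")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise CurveDataError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class UniaxialCurve:
    """One specimen's uniaxial tensile record.

    ``strain_eng``/``stress_eng`` are the measured engineering quantities;
    ``stretch``/``stress_true`` are filled by :func:`pugraft.preprocess.to_true`
    and stay ``None`` until then.
    """

    specimen_id: str
    composition_label: str
    hydration_state: str
    strain_eng: np.ndarray
    stress_eng: np.ndarray
    stretch: Optional[np.ndarray] = None
    stress_true: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.strain_eng = _as_float_array(self.strain_eng, "strain_eng")
        self.stress_eng = _as_float_array(self.stress_eng, "stress_eng")
        if self.hydration_state not in HYDRATION_STATES:
            raise CurveDataError(
                f"hydration_state must be one of {HYDRATION_STATES}, "
                f"got {self.hydration_state!r}"
            )
        n = self.strain_eng.size
        if self.stress_eng.size != n:
            raise CurveDataError(
                f"strain and stress lengths differ ({n} vs {self.stress_eng.size})"
            )
        if n < 3:
            raise CurveDataError(f"curve needs at least 3 points, got {n}")
        if not np.all(np.isfinite(self.strain_eng)) or not np.all(
            np.isfinite(self.stress_eng)
        ):
            raise CurveDataError("curve contains non-finite values")
        if self.strain_eng[0] < 0:
            raise CurveDataError(
                f"first strain value must be >= 0, got {self.strain_eng[0]}"
            )
        diffs = np.diff(self.strain_eng)
        bad = np.flatnonzero(diffs <= 0)
        if bad.size:
            raise CurveDataError(
                "strain must be strictly increasing; violation at row "
                f"{bad[0] + 2}"  # 1-based data row of the first non-increasing value
            )
        if np.any(self.stress_eng < 0):
            raise CurveDataError("engineering stress must be non-negative")
        if self.stretch is not None:
            self.stretch = _as_float_array(self.stretch, "stretch")
        if self.stress_true is not None:
            self.stress_true = _as_float_array(self.stress_true, "stress_true")

    def __len__(self) -> int:
        return self.strain_eng.size


@dataclass(frozen=True)
class MooneyRivlinParams:
    """Three-parameter Mooney-Rivlin coefficient triple (MPa) with its temperature context.

    No sign constraint is imposed: fitted elastomer coefficient sets routinely
    contain negative entries while the uniaxial response stays monotone over
    the working stretch range.
    """

    c10: float
    c01: float
    c11: float
    temperature: float = 310.15

    def __post_init__(self) -> None:
        for name in ("c10", "c01", "c11"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if not (np.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    def scaled(self, factor: float) -> "MooneyRivlinParams":
        """All three coefficients multiplied by ``factor`` (temperature kept)."""
        return replace(
            self,
            c10=self.c10 * factor,
            c01=self.c01 * factor,
            c11=self.c11 * factor,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.c10, self.c01, self.c11])


@dataclass(frozen=True)
class FitResult:
    """A fitted coefficient triple with goodness-of-fit and derived quantities.

    ``rmse`` (MPa) and ``ccc`` (Lin's concordance, dimensionless) are computed
    on true stress; ``crosslink_density`` is in kmol/m^3; ``initial_slope`` is
    d(sigma_1)/d(lambda) at lambda = 1, i.e. 6*(C10 + C01), in MPa.
    """

    params: MooneyRivlinParams
    rmse: float
    ccc: float
    crosslink_density: float
    n_points: int
    initial_slope: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError(f"rmse must be >= 0, got {self.rmse}")
        if abs(self.ccc) > 1 + 1e-12:
            raise ValueError(f"|ccc| must be <= 1, got {self.ccc}")
        if self.crosslink_density < 0:
            raise ValueError(
                f"crosslink_density must be >= 0, got {self.crosslink_density}"
            )


@dataclass(frozen=True)
class PressureWaveform:
    """Sinusoidal arterial pressure P(t) = Pm * (1 + eps * sin(2*pi*f*t)).

    ``p_max``/``p_min`` are the physiological systolic/diastolic extremes the
    mean was derived from; the waveform itself oscillates between
    ``p_mean * (1 - epsilon)`` and ``p_mean * (1 + epsilon)``.  ``omega`` is
    the cardiac frequency in Hz.
    """

    p_max: float
    p_min: float
    p_mean: float
    amplitude_ps: float
    epsilon: float
    omega: float

    def __post_init__(self) -> None:
        if not (self.p_min < self.p_mean < self.p_max):
            raise ValueError(
                "require p_min < p_mean < p_max, got "
                f"({self.p_min}, {self.p_mean}, {self.p_max})"
            )
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0 Hz, got {self.omega}")
        if self.amplitude_ps < 0:
            raise ValueError(f"amplitude_ps must be >= 0, got {self.amplitude_ps}")
        expected_eps = self.amplitude_ps / self.p_mean
        if not np.isclose(self.epsilon, expected_eps, rtol=1e-9, atol=1e-12):
            raise ValueError(
                f"epsilon ({self.epsilon}) must equal amplitude_ps / p_mean "
                f"({expected_eps})"
            )


@dataclass(frozen=True)
class GraftGeometry:
    """Undeformed tube geometry: inner radius r0 and wall thickness h, both in mm."""

    inner_radius_r0: float
    thickness_h: float

    def __post_init__(self) -> None:
        if self.inner_radius_r0 <= 0 or self.thickness_h <= 0:
            raise ValueError(
                "geometry must be positive, got "
                f"r0={self.inner_radius_r0}, h={self.thickness_h}"
            )


@dataclass
class ComplianceSeries:
    """Time-resolved response of one graft geometry under one waveform.

    ``compliance`` is the forward-difference distensibility
    (r_{i+1} - r_i) / (r_i * (P_{i+1} - P_i)) in 1/mmHg; it has one element
    fewer than ``time`` and holds NaN gaps where |dP| falls below the
    turning-point threshold.
    """

    time: np.ndarray            # s
    pressure: np.ndarray        # mmHg
    hoop_stress: np.ndarray     # MPa
    stretch: np.ndarray         # dimensionless
    radius: np.ndarray          # mm
    compliance: np.ndarray      # 1/mmHg, length len(time) - 1

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("pressure", "hoop_stress", "stretch", "radius"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length {n}")
        if len(self.compliance) != n - 1:
            raise ValueError(
                f"compliance must have length {n - 1}, got {len(self.compliance)}"
            )
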