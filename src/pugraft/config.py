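"""Run configuration: schema, defaults, loading, validation.

A run config is a single YAML or JSON document.  Defaults reproduce the
study conditions: four material compositions fitted at body temperature
(310.15 K) and swept under a 180/40 mmHg sinusoidal waveform over small
frequency and geometry grids.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .datamodel import ConfigError, MooneyRivlinParams

__all__ = ["MaterialSpec", "RunConfig", "load_config", "config_hash", "TABLE_COEFFICIENTS"]

#: Reference hydrated-material coefficient triples (MPa) used as the default
#: ground truth for synthetic runs; labels follow the PEG-PCL-PE w/w recipe.
TABLE_COEFFICIENTS: Dict[str, tuple] = {
    "5-90-5": (0.589, -0.416, -0.0399),
    "45-45-10": (-1.41, 3.03, 0.223),
    "46.3-46.3-7.5": (-0.854, 1.82, 0.132),
    "47.5-47.5-5": (-0.812, 1.66, 0.101),
}


@dataclass
class MaterialSpec:
    """One material: either curve files on disk or a synthetic ground truth."""

    label: str
    hydration_state: str = "hydrated"
    curve_files: List[str] = field(default_factory=list)
    true_params: Optional[MooneyRivlinParams] = None

    def is_synthetic(self) -> bool:
        return self.true_params is not None


@dataclass
class RunConfig:
    materials: List[MaterialSpec]
    temperature: float = 310.15
    # waveform
    p_max: float = 180.0
    p_min: float = 40.0
    amplitude_ps: float = 10.0
    # sweep grids
    omega_grid: List[float] = field(default_factory=lambda: [1.0, 1.5, 2.0])
    r0_grid: List[float] = field(default_factory=lambda: [1.5, 2.0, 3.0])
    h_grid: List[float] = field(default_factory=lambda: [0.3, 0.4, 0.5])
    samples_per_cycle: int = 256
    n_cycles: int = 3
    # synthetic generation
    lambda_max: float = 2.5
    n_points: int = 200
    n_replicates: int = 5
    noise_sd: float = 0.02
    replicate_jitter_cv: float = 0.05
    seed: int = 0
    strain_unit: str = "fraction"
    delimiter: Optional[str] = None
    n_grid: int = 200

    def validate(self) -> None:
        if not self.materials:
            raise ConfigError("materials list must be non-empty")
        if self.samples_per_cycle < 16:
            raise ConfigError(
                f"samples_per_cycle must be >= 16, got {self.samples_per_cycle}"
            )
        for name in ("omega_grid", "r0_grid", "h_grid"):
            if not getattr(self, name):
                raise ConfigError(f"{name} must be non-empty")
        if self.temperature <= 0:
            raise ConfigError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.p_min < self.p_max:
            raise ConfigError("require p_min < p_max")
        if self.strain_unit not in ("fraction", "percent"):
            raise ConfigError(f"unknown strain_unit {self.strain_unit!r}")
        for m in self.materials:
            if not m.is_synthetic() and not m.curve_files:
                raise ConfigError(
                    f"material {m.label!r} needs either curve_files or true_params"
                )


def default_config(seed: int = 0) -> RunConfig:
    """All four reference compositions, synthetic, hydrated, study waveform."""
    materials = [
        MaterialSpec(label=label, true_params=MooneyRivlinParams(*coeffs))
        for label, coeffs in TABLE_COEFFICIENTS.items()
    ]
    return RunConfig(materials=materials, seed=seed)


def _to_dict(raw) -> dict:
    if not isinstance(raw, dict):
        raise ConfigError(f"config document must be a mapping, got {type(raw).__name__}")
    return raw


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    raw = _to_dict(yaml.safe_load(text))

    materials = []
    for entry in raw.get("materials", []):
        entry = dict(entry)
        tp = entry.pop("true_params", None)
        if tp is not None:
            tp = MooneyRivlinParams(
                c10=float(tp["c10"]),
                c01=float(tp["c01"]),
                c11=float(tp["c11"]),
                temperature=float(tp.get("temperature", raw.get("temperature", 310.15))),
            )
        materials.append(
            MaterialSpec(
                label=str(entry.pop("label")),
                hydration_state=entry.pop("hydration_state", "hydrated"),
                curve_files=list(entry.pop("curve_files", [])),
                true_params=tp,
            )
        )
        if entry:
            raise ConfigError(f"unknown material keys: {sorted(entry)}")

    known = {f for f in RunConfig.__dataclass_fields__ if f != "materials"}
    extra = {k: v for k, v in raw.items() if k != "materials"}
    unknown = set(extra) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(materials=materials, **extra)
    cfg.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the canonicalised config (for run manifests)."""

    def encode(obj):
        if isinstance(obj, MaterialSpec):
            return {
                "label": obj.label,
                "hydration_state": obj.hydration_state,
                "curve_files": obj.curve_files,
                "true_params": encode(obj.true_params) if obj.true_params else None,
            }
        if isinstance(obj, MooneyRivlinParams):
            return [obj.c10, obj.c01, obj.c11, obj.temperature]
        raise TypeError(type(obj))

    payload = {
        k: ([encode(m) for m in v] if k == "materials" else v)
        for k, v in vars(cfg).items()
    }
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()
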