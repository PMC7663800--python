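"""Reading specimen curve files and writing result tables.

Curve files are delimited text (comma or tab, auto-detected) with a header
naming a strain column and a stress column in MPa; strain may be a fraction
or percent.  All result tables round-trip through
:func:`pandas.DataFrame.to_csv` at full float precision (``%.17g``), so a
write-then-read cycle reproduces every value bit-for-bit.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    ComplianceSeries,
    CurveDataError,
    CurveFormatError,
    FitResult,
    MooneyRivlinParams,
    UniaxialCurve,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"

FIT_COLUMNS = [
    "label",
    "C10",
    "C01",
    "C11",
    "v",
    "RMSE",
    "CCC",
    "temperature_K",
    "n_points",
    "initial_slope",
]

COMPLIANCE_COLUMNS = [
    "material",
    "r0_mm",
    "h_mm",
    "omega_hz",
    "time_s",
    "pressure_mmHg",
    "hoop_stress_MPa",
    "stretch",
    "radius_mm",
    "compliance_per_mmHg",
]


def _find_column(columns: Sequence[str], stem: str) -> Optional[str]:
    for col in columns:
        if col.strip().lower().startswith(stem):
            return col
    return None


def read_curve_file(
    path,
    strain_unit: str = "fraction",
    delimiter: Optional[str] = None,
    composition_label: str = "",
    hydration_state: str = "non_hydrated",
) -> List[UniaxialCurve]:
    """Read one delimited curve file into validated curves.

    The file must carry a ``strain`` column and a ``stress_MPa`` column (any
    header starting with ``strain``/``stress`` is accepted, case-insensitive).
    A header named ``strain_pct`` or ``strain_percent`` forces percent
    interpretation regardless of ``strain_unit``.  Rows with non-finite
    values are dropped with a logged count.  An optional ``specimen_id``
    column splits the file into one curve per specimen, in file order.

    Raises
    ------
    CurveFormatError
        Missing strain or stress column.
    CurveDataError
        Fewer than 3 valid rows, or non-monotone strain (the message names
        the first offending row).
    """
    path = Path(path)
    if strain_unit not in ("fraction", "percent"):
        raise ValueError(f"strain_unit must be 'fraction' or 'percent', got {strain_unit!r}")
    if delimiter is None:
        # comma/tab auto-detect on the header line; round_trip parsing keeps
        # the write -> read cycle exact to the last bit
        header = path.open().readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")

    strain_col = _find_column(df.columns, "strain")
    stress_col = _find_column(df.columns, "stress")
    if strain_col is None or stress_col is None:
        raise CurveFormatError(
            f"{path.name}: need 'strain' and 'stress_MPa' columns, "
            f"found {list(df.columns)}"
        )
    percent = strain_unit == "percent" or strain_col.strip().lower() in (
        "strain_pct",
        "strain_percent",
    )

    id_col = _find_column(df.columns, "specimen_id")
    groups: List[Tuple[str, pd.DataFrame]]
    if id_col is not None:
        seen: Dict[str, pd.DataFrame] = {}
        for sid, g in df.groupby(id_col, sort=False):
            seen[str(sid)] = g
        groups = list(seen.items())
    else:
        groups = [(path.stem, df)]

    curves = []
    for sid, g in groups:
        strain = pd.to_numeric(g[strain_col], errors="coerce").to_numpy(float)
        stress = pd.to_numeric(g[stress_col], errors="coerce").to_numpy(float)
        keep = np.isfinite(strain) & np.isfinite(stress)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("%s[%s]: dropped %d non-finite rows", path.name, sid, dropped)
        strain, stress = strain[keep], stress[keep]
        if strain.size < 3:
            raise CurveDataError(
                f"{path.name}[{sid}]: only {strain.size} valid rows; need >= 3"
            )
        if percent:
            strain = strain / 100.0
        try:
            curves.append(
                UniaxialCurve(
                    specimen_id=sid,
                    composition_label=composition_label,
                    hydration_state=hydration_state,
                    strain_eng=strain,
                    stress_eng=stress,
                )
            )
        except CurveDataError as exc:
            raise CurveDataError(f"{path.name}[{sid}]: {exc}") from exc
    return curves


def write_curve(curve: UniaxialCurve, path) -> None:
    """Write one curve as CSV with ``strain``/``stress_MPa``/``specimen_id`` columns."""
    pd.DataFrame(
        {
            "strain": curve.strain_eng,
            "stress_MPa": curve.stress_eng,
            "specimen_id": curve.specimen_id,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_fit_results(results: Sequence[Tuple[str, FitResult]], path) -> None:
    """Flat per-material fit table: label, C10, C01, C11, v, RMSE, CCC (+ context)."""
    rows = []
    for label, fr in results:
        rows.append(
            {
                "label": label,
                "C10": fr.params.c10,
                "C01": fr.params.c01,
                "C11": fr.params.c11,
                "v": fr.crosslink_density,
                "RMSE": fr.rmse,
                "CCC": fr.ccc,
                "temperature_K": fr.params.temperature,
                "n_points": fr.n_points,
                "initial_slope": fr.initial_slope,
            }
        )
    pd.DataFrame(rows, columns=FIT_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_fit_results(path) -> List[Tuple[str, FitResult]]:
    """Inverse of :func:`write_fit_results`."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        params = MooneyRivlinParams(
            c10=float(row["C10"]),
            c01=float(row["C01"]),
            c11=float(row["C11"]),
            temperature=float(row["temperature_K"]),
        )
        out.append(
            (
                str(row["label"]),
                FitResult(
                    params=params,
                    rmse=float(row["RMSE"]),
                    ccc=float(row["CCC"]),
                    crosslink_density=float(row["v"]),
                    n_points=int(row["n_points"]),
                    initial_slope=float(row["initial_slope"]),
                ),
            )
        )
    return out


def write_compliance_long(
    cells: Sequence[Tuple[str, float, float, float, ComplianceSeries]], path
) -> None:
    """Long-format compliance table, one row per time sample per grid cell.

    ``cells`` holds (material, r0, h, omega, series) tuples.  The compliance
    column is one element shorter than the time grid; the final sample of
    each cell carries an empty compliance field, as do turning-point gaps.
    """
    frames = []
    for material, r0, h, omega, cs in cells:
        comp = np.append(cs.compliance, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "material": material,
                    "r0_mm": r0,
                    "h_mm": h,
                    "omega_hz": omega,
                    "time_s": cs.time,
                    "pressure_mmHg": cs.pressure,
                    "hoop_stress_MPa": cs.hoop_stress,
                    "stretch": cs.stretch,
                    "radius_mm": cs.radius,
                    "compliance_per_mmHg": comp,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=COMPLIANCE_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
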