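#!/usr/bin/env python
"""Fit the three-parameter Mooney-Rivlin model to each composition's
replicate-averaged true stress-stretch curve.

Reads the replicate CSVs produced by 01_generate_tensile_curves.py, converts
to true measures, averages the five replicates per composition on a common
stretch grid, fits (C10, C01, C11) by linear least squares, and reports RMSE,
Lin's CCC, the crosslink density v = |C10|/(RT) at 310.15 K, and the initial
stiffness 6(C10+C01).

Writes results/fit_results.csv.
"""

from pathlib import Path

from pugraft.curve_io import read_curve_file, write_fit_results
from pugraft.config import TABLE_COEFFICIENTS
from pugraft.hyperelastic import fit
from pugraft.preprocess import average_curves, to_true

ROOT = Path(__file__).resolve().parents[1]
CURVES = ROOT / "results" / "curves"
OUT = ROOT / "results" / "fit_results.csv"


def main() -> None:
    if not CURVES.is_dir():
        raise SystemExit("run analysis/01_generate_tensile_curves.py first")
    results = []
    for label in TABLE_COEFFICIENTS:
        curves = []
        for path in sorted(CURVES.glob(f"{label}-r*.csv")):
            curves += read_curve_file(
                path, composition_label=label, hydration_state="hydrated"
            )
        avg = average_curves([to_true(c) for c in curves])
        fr = fit(avg.stretch_grid, avg.stress_true_mean, temperature=310.15)
        results.append((label, fr))
        p = fr.params
        print(
            f"{label}: C10={p.c10:+.3f} C01={p.c01:+.3f} C11={p.c11:+.4f} MPa | "
            f"v={fr.crosslink_density:.2f} kmol/m^3 | RMSE={fr.rmse:.3f} MPa | "
            f"CCC={fr.ccc:.4f} | initial slope {fr.initial_slope:.2f} MPa"
        )
    write_fit_results(results, OUT)
    print(f"fit table written to {OUT}")


if __name__ == "__main__":
    main()
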