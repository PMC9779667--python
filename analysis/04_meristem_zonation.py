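#!/usr/bin/env python
"""Root-apical-meristem zonation per condition.

Reads results/data/cellfiles.csv and results/data/mitotic.csv; fits the
two-Gaussian cell-length mixture per condition, counts meristematic,
isodiametric and transition cells per root, measures mature and
first-elongated cell lengths, smooths positional length/width/anisotropy
curves, and summarises mitotic counts with pairwise fold-changes.  Writes
results/zonation.csv, zonation_summary.csv, curves.csv and mitotic.csv."""

from pathlib import Path

import numpy as np
import pandas as pd

from seedscreen.io import read_measurements, write_csv
from seedscreen.meristem import analyze_zonation, mature_cell_length, mitotic_summary, positional_curve
from seedscreen.synthgen import frame_to_cell_files

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    files = frame_to_cell_files(read_measurements(ROOT / "data" / "cellfiles.csv", "cellfile"))
    zon, fits = analyze_zonation(files)
    zdf = pd.DataFrame([{k: v for k, v in vars(z).items() if k != "labels"} for z in zon])
    write_csv(zdf, ROOT / "zonation.csv")

    rows = []
    for cond in sorted(fits):
        pool = np.concatenate([f.lengths for f in files if f.condition == cond])
        sub = zdf[zdf["condition"] == cond]
        rows.append({
            "condition": cond,
            "mu_short_um": round(fits[cond].mu_short, 2),
            "mu_long_um": round(fits[cond].mu_long, 2),
            "meristem_cells_gmm": round(sub["meristem_cell_count_gmm"].mean(), 1),
            "isodiametric": round(sub["isodiametric_count"].mean(), 1),
            "transition": round(sub["transition_count"].mean(), 1),
            "first_elongated_um": round(sub["first_elongated_length"].mean(), 1),
            "mature_um": round(mature_cell_length(pool, k=10), 1),
        })
    summary = pd.DataFrame(rows)
    write_csv(summary, ROOT / "zonation_summary.csv")
    print("per-condition zonation summary:")
    print(summary.to_string(index=False))

    curve_rows = []
    for cond in sorted(fits):
        cond_files = [f for f in files if f.condition == cond]
        for var in ("length", "width", "anisotropy"):
            c = positional_curve(cond_files, variable=var, seed=SEED)
            for i, x in enumerate(c.grid):
                curve_rows.append({"condition": cond, "variable": var,
                                   "cell_index": int(x), "fit": c.fit[i],
                                   "lower": c.lower[i], "upper": c.upper[i]})
            if var == "length":
                print(f"{cond}: steepest length slope {c.max_slope:.1f} µm/cell "
                      f"at index {c.max_slope_index} (elongation onset region)")
    write_csv(pd.DataFrame(curve_rows), ROOT / "curves.csv")

    mito = read_measurements(ROOT / "data" / "mitotic.csv", "mitotic")
    counts = {c: g["count"].to_numpy() for c, g in mito.groupby("condition")}
    means, folds = mitotic_summary(counts)
    write_csv(folds, ROOT / "mitotic.csv")
    print("\nmitotic index means:", {k: round(v, 2) for k, v in means.items()})
    dw = folds[(folds["condition_a"] == "dark") & (folds["condition_b"] == "darkW")]
    if len(dw):
        print(f"darkW/dark mitotic fold-change: {1 / dw['fold_change'].iloc[0]:.1f}x")


if __name__ == "__main__":
    main()
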