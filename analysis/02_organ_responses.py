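#!/usr/bin/env python
"""Per-replicate organ responses and response quotients.

Reads results/data/screen.csv, computes for every genotype and biological
replicate the dark/darkW responses, the hypocotyl/root ratio adjustment, the
wild-type-normalised RQs and the response P-values, and writes
results/replicates.csv.  Prints the mean RQ_ratio per genotype — the
screen's main decision readout."""

from pathlib import Path

import pandas as pd

from seedscreen.io import read_measurements, write_csv
from seedscreen.organ_stats import summarize_screen

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_measurements(ROOT / "data" / "screen.csv", "organ")
    summaries = summarize_screen(records)
    rep = pd.DataFrame([vars(s) for s in summaries])
    write_csv(rep, ROOT / "replicates.csv")
    print(f"{len(rep)} replicate summaries -> {ROOT / 'replicates.csv'}\n")
    table = rep.groupby("genotype_id")[["rq_hypocotyl", "rq_root", "rq_ratio",
                                        "p_ratio"]].mean().round(3)
    print("mean over replicates (RQ = 1 is wild-type-like):")
    print(table.to_string())


if __name__ == "__main__":
    main()
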