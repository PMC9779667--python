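#!/usr/bin/env python
"""Genotype-level classification: volcano coordinates, confused calls and
the three-criterion decision-mutant calls.

Reads results/data/screen.csv, aggregates replicates per genotype (mean RQ,
median P), classifies each genotype and writes results/genotypes.csv plus a
volcano plot with the 0.8/1.2 RQ and 0.05/1e-5 P guide lines."""

from pathlib import Path

from seedscreen.decision import classify_screen, volcano_plot
from seedscreen.io import read_measurements, write_csv
from seedscreen.organ_stats import aggregate_genotype, summarize_screen

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_measurements(ROOT / "data" / "screen.csv", "organ")
    summaries = summarize_screen(records)
    agg = {g: aggregate_genotype([s for s in summaries if s.genotype_id == g])
           for g in records["genotype_id"].unique()}
    calls = classify_screen(records, agg)
    write_csv(calls, ROOT / "genotypes.csv")
    volcano_plot(calls, str(ROOT / "volcano.svg"))
    print(f"{len(calls)} genotypes -> {ROOT / 'genotypes.csv'} (+ volcano.svg)\n")
    cols = ["genotype_id", "mean_rq_ratio", "median_p_ratio", "rq_label",
            "p_label", "confused", "decision_mutant", "criteria_met"]
    print(calls[cols].round(3).to_string(index=False))
    n_conf = int(calls["confused"].sum())
    n_dec = int(calls["decision_mutant"].sum())
    print(f"\n{n_conf} confused genotype(s); {n_dec} decision mutant(s) "
          "(all three criteria: ratio failure, weak significance, organ exceedance)")


if __name__ == "__main__":
    main()
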