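#!/usr/bin/env python
"""Simulate the screen's raw data: seedling organ measurements for every
response class, root epidermal cell files per condition, and mitotic-marker
counts.  Writes the three input tables under results/data/."""

from pathlib import Path

from seedscreen.io import write_csv
from seedscreen.synthgen import (
    DEFAULT_CELLFILE_SPECS,
    DEFAULT_CONDITIONS,
    DEFAULT_MITOTIC_MEANS,
    cell_files_to_frame,
    demo_genotypes,
    generate_cell_files,
    generate_mitotic_counts,
    generate_screen_dataset,
)

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    conditions = {k: DEFAULT_CONDITIONS[k] for k in ("dark", "darkW")}
    screen = generate_screen_dataset(
        conditions, demo_genotypes(), n_per_group=40,
        n_replicates=3, n_plates=2, seed=SEED)
    write_csv(screen, OUT / "screen.csv")
    print(f"screen: {len(screen)} seedlings, "
          f"{screen['genotype_id'].nunique()} genotypes, "
          f"{screen['replicate_id'].nunique()} replicates -> {OUT / 'screen.csv'}")

    files = generate_cell_files(DEFAULT_CELLFILE_SPECS, n_roots=15, seed=SEED + 1)
    cells = cell_files_to_frame(files)
    write_csv(cells, OUT / "cellfiles.csv")
    print(f"cell files: {len(files)} roots, {len(cells)} cells -> {OUT / 'cellfiles.csv'}")

    mitotic = generate_mitotic_counts(DEFAULT_MITOTIC_MEANS, n_roots=30, seed=SEED + 2)
    write_csv(mitotic, OUT / "mitotic.csv")
    print(f"mitotic counts: {len(mitotic)} root tips -> {OUT / 'mitotic.csv'}")


if __name__ == "__main__":
    main()
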