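"""End-to-end pipeline: simulate (or read) a screen, compute response
quotients and decision calls, run the zonation analysis, and write a
reproducible result bundle (CSVs plus a run manifest)."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InputError
from .io import read_measurements, write_csv
from .decision import classify_screen
from .meristem import analyze_zonation, mature_cell_length, mitotic_summary, positional_curve
from .organ_stats import aggregate_genotype, summarize_screen
from .synthgen import (
    DEFAULT_CELLFILE_SPECS,
    DEFAULT_CONDITIONS,
    DEFAULT_MITOTIC_MEANS,
    CellFileSpec,
    ConditionSpec,
    GenotypeSpec,
    cell_files_to_frame,
    demo_genotypes,
    frame_to_cell_files,
    generate_cell_files,
    generate_mitotic_counts,
    generate_screen_dataset,
)

log = logging.getLogger("seedscreen")


@dataclass
class PipelineConfig:
    """Configuration for one reproducible run.

    When ``organ_csv``/``cellfile_csv``/``mitotic_csv`` are unset, data are
    simulated from the condition/genotype/cell-file specs (defaults emulate
    the optimized screen conditions).  The seed is mandatory: every
    stochastic stage derives from it.
    """

    seed: int = 0
    out_dir: str = "results"
    # inputs (optional; simulated when absent)
    organ_csv: str | None = None
    cellfile_csv: str | None = None
    mitotic_csv: str | None = None
    # generator settings
    conditions: dict = field(default_factory=dict)  # name -> ConditionSpec kwargs
    genotypes: list = field(default_factory=list)  # list of GenotypeSpec kwargs
    n_per_group: int = 40
    n_replicates: int = 3
    n_plates: int = 2
    n_roots: int = 20
    cellfile_specs: dict = field(default_factory=dict)  # condition -> CellFileSpec kwargs
    mitotic_means: dict = field(default_factory=dict)
    # analysis thresholds
    dark: str = "dark"
    darkW: str = "darkW"
    rq_attenuated: float = 0.8
    rq_exaggerated: float = 1.2
    p_insignificant: float = 0.05
    p_attenuated: float = 1e-5
    posterior_cutoff: float = 0.8
    transition_factor: float = 1.5
    k_mature: int = 10
    # smoothing
    span: float = 0.75
    degree: int = 2
    ci: float = 0.95
    n_boot: int = 200

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if not self.rq_attenuated < self.rq_exaggerated:
            raise ConfigurationError("RQ lower bound must be below upper bound")
        if not 0 < self.p_attenuated < self.p_insignificant <= 1:
            raise ConfigurationError("P thresholds must satisfy 0 < attenuated < insignificant <= 1")
        if not 0 < self.posterior_cutoff < 1:
            raise ConfigurationError("posterior_cutoff must lie in (0, 1)")
        if self.transition_factor <= 1:
            raise ConfigurationError("transition_factor must be > 1")
        if not 0 < self.span <= 1 or self.degree not in (1, 2):
            raise ConfigurationError("invalid smoothing parameters")
        if self.n_per_group < 2 or self.k_mature < 1 or self.n_boot < 1:
            raise ConfigurationError("invalid sample-size parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved_conditions(self) -> dict[str, ConditionSpec]:
        if not self.conditions:
            return {k: DEFAULT_CONDITIONS[k] for k in ("dark", "darkW")}
        return {name: ConditionSpec(name=name, **kw) for name, kw in self.conditions.items()}

    def resolved_genotypes(self) -> list[GenotypeSpec]:
        if not self.genotypes:
            return demo_genotypes()
        return [GenotypeSpec(**kw) for kw in self.genotypes]

    def resolved_cellfile_specs(self) -> dict[str, CellFileSpec]:
        if not self.cellfile_specs:
            return dict(DEFAULT_CELLFILE_SPECS)
        return {name: CellFileSpec(**kw) for name, kw in self.cellfile_specs.items()}

    def resolved_mitotic_means(self) -> dict[str, float]:
        return dict(self.mitotic_means) or dict(DEFAULT_MITOTIC_MEANS)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _derive_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the result bundle under ``config.out_dir``.

    Outputs: replicates.csv (per-replicate RQs and P-values), genotypes.csv
    (aggregates, labels and decision calls), zonation.csv (per-root metrics),
    zonation_summary.csv, curves.csv (loess fits with CI), mitotic.csv and
    manifest.json.  Identical config + seed reproduce the bundle
    byte-for-byte; on failure, partial outputs are removed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        # --- organ stage
        if config.organ_csv:
            records = read_measurements(config.organ_csv, "organ")
            log.info("read %d seedling rows from %s", len(records), config.organ_csv)
        else:
            records = generate_screen_dataset(
                config.resolved_conditions(), config.resolved_genotypes(),
                n_per_group=config.n_per_group, n_replicates=config.n_replicates,
                n_plates=config.n_plates, seed=_derive_seed(config.seed, "screen"))
            log.info("simulated %d seedling rows", len(records))

        summaries = summarize_screen(records, dark=config.dark, darkW=config.darkW)
        rep_df = pd.DataFrame([vars(s) for s in summaries])
        written["replicates"] = write_csv(rep_df, out / "replicates.csv")

        agg = {}
        for gid in rep_df["genotype_id"].unique():
            agg[gid] = aggregate_genotype([s for s in summaries if s.genotype_id == gid])
        calls = classify_screen(records, agg, dark=config.dark, darkW=config.darkW)
        n_reps = {g: a.n_replicates for g, a in agg.items()}
        calls.insert(2, "n_replicates", calls["genotype_id"].map(n_reps))
        calls.insert(3, "replication", calls["genotype_id"].map(
            lambda g: agg[g].replication))
        written["genotypes"] = write_csv(calls, out / "genotypes.csv")
        log.info("classified %d genotypes (%d decision mutants)",
                 len(calls), int(calls["decision_mutant"].sum()))

        # --- zonation stage
        if config.cellfile_csv:
            files = frame_to_cell_files(read_measurements(config.cellfile_csv, "cellfile"))
        else:
            files = generate_cell_files(
                config.resolved_cellfile_specs(), n_roots=config.n_roots,
                seed=_derive_seed(config.seed, "cellfiles"))
        log.info("zonation on %d cell files", len(files))
        zon, fits = analyze_zonation(files, threshold=config.posterior_cutoff,
                                     k_mature=config.k_mature)
        zon_df = pd.DataFrame([{k: v for k, v in vars(z).items() if k != "labels"}
                               for z in zon])
        written["zonation"] = write_csv(zon_df, out / "zonation.csv")

        summary_rows = []
        for cond in sorted({f.condition for f in files}):
            pool = np.concatenate([f.lengths for f in files if f.condition == cond])
            sub = zon_df[zon_df["condition"] == cond]
            summary_rows.append({
                "condition": cond,
                "n_roots": len(sub),
                "mu_short": fits[cond].mu_short,
                "mu_long": fits[cond].mu_long,
                "weight_short": fits[cond].weight_short,
                "mean_meristem_count_gmm": sub["meristem_cell_count_gmm"].mean(),
                "mean_isodiametric": sub["isodiametric_count"].mean(),
                "mean_transition": sub["transition_count"].mean(),
                "mean_first_elongated_um": sub["first_elongated_length"].mean(),
                "mature_cell_length_um": mature_cell_length(pool, k=config.k_mature),
            })
        written["zonation_summary"] = write_csv(
            pd.DataFrame(summary_rows), out / "zonation_summary.csv")

        curve_rows = []
        for cond in sorted({f.condition for f in files}):
            cond_files = [f for f in files if f.condition == cond]
            for var in ("length", "width", "anisotropy"):
                curve = positional_curve(
                    cond_files, variable=var, span=config.span, degree=config.degree,
                    ci=config.ci, n_boot=config.n_boot,
                    seed=_derive_seed(config.seed, f"boot:{cond}:{var}"))
                for i, x in enumerate(curve.grid):
                    curve_rows.append({
                        "condition": cond, "variable": var, "cell_index": int(x),
                        "fit": curve.fit[i], "lower": curve.lower[i],
                        "upper": curve.upper[i],
                    })
        written["curves"] = write_csv(pd.DataFrame(curve_rows), out / "curves.csv")

        # --- mitotic stage
        if config.mitotic_csv:
            mito = read_measurements(config.mitotic_csv, "mitotic")
        else:
            mito = generate_mitotic_counts(
                config.resolved_mitotic_means(), n_roots=config.n_roots,
                seed=_derive_seed(config.seed, "mitotic"))
        counts = {c: g["count"].to_numpy() for c, g in mito.groupby("condition", sort=True)}
        means, folds = mitotic_summary(counts)
        folds.insert(0, "mean_a", folds["condition_a"].map(means))
        folds.insert(1, "mean_b", folds["condition_b"].map(means))
        written["mitotic"] = write_csv(folds, out / "mitotic.csv")

        manifest = {
            "package": "seedscreen",
            "version": __version__,
            "python": sys.version.split()[0],
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "config": asdict(config),
            "outputs": {k: str(v) for k, v in written.items()},
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        written["manifest"] = manifest_path
        return written
    except Exception:
        for p in written.values():
            try:
                p.unlink()
            except OSError:
                pass
        raise
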