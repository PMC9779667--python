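"""Synthetic seedling-screen and cell-file generator.

The screen this package analyses places germinating Arabidopsis seedlings in
a conflict-of-interest between hypocotyl growth (favoured by darkness) and
primary root growth (favoured by water withdrawal, imposed with PEG).  The
generator emulates the statistical structure of such a screen — condition-
dependent organ-length distributions, multiplicative plate/PEG-lot effects,
genotype response classes — and, for the root-tip analyses, epidermal cell
files with a short-cell meristem followed by a geometric elongation zone,
plus Poisson mitotic-marker counts.

Everything is a pure function of (configuration, seed): identical inputs
yield byte-identical tables.

Units: organ lengths and widths in mm, cell measurements in µm, water
potential in MPa (≤ 0), light intensity in µmol m⁻² s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

ORGAN_COLUMNS = [
    "genotype_id",
    "ecotype_ref",
    "plate_id",
    "replicate_id",
    "condition",
    "hypocotyl_length_mm",
    "root_length_mm",
    "hypocotyl_width_mm",
]

CELLFILE_COLUMNS = [
    "root_id",
    "condition",
    "genotype_id",
    "cell_index",
    "length_um",
    "width_um",
]

RESPONSE_CLASSES = (
    "normal",
    "attenuated",
    "exaggerated",
    "inverse",
    "confused",
    "perception_null",
)


@dataclass(frozen=True)
class ConditionSpec:
    """Per-condition organ-length distributions (per-seedling Gaussians)."""

    name: str
    water_potential: float = 0.0  # MPa, <= 0
    light_intensity: float = 0.0  # µmol m⁻² s⁻¹, >= 0
    hypocotyl_mean: float = 10.0  # mm
    hypocotyl_sd: float = 1.5
    root_mean: float = 3.0
    root_sd: float = 0.8
    hypocotyl_width_mean: float = 0.25
    hypocotyl_width_sd: float = 0.03

    def __post_init__(self):
        if self.water_potential > 0:
            raise ConfigurationError(f"water_potential must be <= 0 MPa, got {self.water_potential}")
        if self.light_intensity < 0:
            raise ConfigurationError("light_intensity must be >= 0")
        for attr in ("hypocotyl_mean", "hypocotyl_sd", "root_mean", "root_sd",
                     "hypocotyl_width_mean", "hypocotyl_width_sd"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"{attr} must be > 0, got {getattr(self, attr)}")


@dataclass(frozen=True)
class GenotypeSpec:
    """A genotype and how its water-stress response deviates from wild type.

    The multipliers act on the dark→darkW *response* (dark mean / darkW mean)
    relative to the paired wild type, so a downstream response quotient of a
    ``normal``-class genotype with multipliers 1 is centred on 1, and an
    ``attenuated`` genotype with ``hypocotyl_multiplier`` 0.6 is centred on
    RQ_hypocotyl = 0.6.  ``confused`` genotypes ignore water withdrawal
    entirely (darkW organ means equal their dark means) and additionally
    inflate per-seedling noise, which is what produces an attenuated ratio
    quotient together with a high response P-value.  ``perception_null``
    genotypes fail to respond to light (light means equal dark means) but
    adjust normally to darkW.
    """

    genotype_id: str
    ecotype_ref: str
    response_class: str = "normal"
    hypocotyl_multiplier: float = 1.0
    root_multiplier: float = 1.0
    noise_inflation: float = 1.0

    def __post_init__(self):
        if self.response_class not in RESPONSE_CLASSES:
            raise ConfigurationError(
                f"unknown response_class {self.response_class!r}; expected one of {RESPONSE_CLASSES}")
        if self.hypocotyl_multiplier <= 0 or self.root_multiplier <= 0:
            raise ConfigurationError("response multipliers must be > 0")
        if self.noise_inflation < 1:
            raise ConfigurationError("noise_inflation must be >= 1")


@dataclass(frozen=True)
class PlateEffect:
    plate_id: str
    scale_hypocotyl: float
    scale_root: float

    def __post_init__(self):
        if self.scale_hypocotyl <= 0 or self.scale_root <= 0:
            raise ConfigurationError("plate scales must be > 0")


@dataclass(frozen=True)
class CellFileSpec:
    """Structure of a root epidermal cell file ordered from the QC.

    Cells 1..``elongation_onset_index`` are short meristematic cells; from
    the onset the expected length grows geometrically by ``elongation_rate``
    per cell until it reaches ``mature_length_mean``, after which cells are
    drawn from the mature-length distribution.  ``n_mature_cells`` mature
    cells are appended so that mature cell length is measurable.
    """

    meristem_cell_count: int = 25
    meristem_length_mean: float = 8.0  # µm
    meristem_length_sd: float = 1.5
    width_mean: float = 16.0
    width_sd: float = 2.0
    elongation_onset_index: int = 25
    elongation_rate: float = 1.25  # per-cell growth factor, > 1
    mature_length_mean: float = 160.0
    mature_length_sd: float = 20.0
    n_mature_cells: int = 10

    def __post_init__(self):
        if self.meristem_cell_count < 1 or self.elongation_onset_index < 1:
            raise ConfigurationError("cell counts must be >= 1")
        if self.elongation_rate <= 1:
            raise ConfigurationError("elongation_rate must be > 1")
        for attr in ("meristem_length_mean", "meristem_length_sd", "width_mean",
                     "width_sd", "mature_length_mean", "mature_length_sd"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"{attr} must be > 0")


@dataclass
class CellFile:
    """Ordered per-cell measurements for one root; index 1 is next to the QC."""

    root_id: str
    condition: str
    genotype_id: str
    lengths: np.ndarray  # µm
    widths: np.ndarray  # µm

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.lengths.shape != self.widths.shape:
            raise InputError("lengths and widths must align")
        if len(self.lengths) < 5:
            raise InputError("a cell file needs at least 5 cells")
        if (self.lengths <= 0).any() or (self.widths <= 0).any():
            raise InputError("cell measurements must be strictly positive")

    def __len__(self) -> int:
        return len(self.lengths)


# ---------------------------------------------------------------------------
# default stated world
#
# The screen's optimized conditions are darkness and darkness with -0.4 MPa
# water stress; light at 40 µmol m⁻² s⁻¹ is the reference for geometry work.
# Per-seedling dispersions are not printed anywhere, so the defaults below
# are plausible magnitudes chosen once: dark gives long hypocotyls and short
# roots, darkW the trade-off with ~3x inflated root variance.

DEFAULT_CONDITIONS = {
    "light": ConditionSpec("light", 0.0, 40.0, 2.0, 0.4, 7.0, 1.5, 0.20, 0.02),
    "dark": ConditionSpec("dark", 0.0, 0.0, 10.0, 1.5, 3.0, 0.8, 0.25, 0.03),
    "darkW": ConditionSpec("darkW", -0.4, 0.0, 5.0, 1.0, 9.0, 3.0, 0.23, 0.03),
    "lightW": ConditionSpec("lightW", -0.4, 40.0, 1.5, 0.35, 6.0, 1.5, 0.20, 0.02),
}

DEFAULT_CELLFILE_SPECS = {
    # darkW: smaller meristem, earlier and steeper elongation, longer first
    # elongated cell; dark: longest mature cells (shortest roots).
    "light": CellFileSpec(30, 8.0, 1.5, 16.0, 2.0, 30, 1.30, 110.0, 15.0),
    "dark": CellFileSpec(25, 8.0, 1.5, 16.0, 2.0, 25, 1.25, 160.0, 20.0),
    "darkW": CellFileSpec(15, 8.5, 1.5, 16.0, 2.0, 15, 1.60, 140.0, 18.0),
}

# mean CycB1,1:GUS-positive cells per root tip; the dark→darkW ratio encodes
# the eight-fold mitotic increase under combined stress.
DEFAULT_MITOTIC_MEANS = {"light": 12.0, "dark": 1.0, "darkW": 8.0}


def demo_genotypes(ecotype: str = "Col-0") -> list[GenotypeSpec]:
    """One genotype per response class, paired to a single wild-type ecotype."""
    return [
        GenotypeSpec(ecotype, ecotype, "normal"),
        GenotypeSpec("mut-normal", ecotype, "normal"),
        GenotypeSpec("mut-attenuated", ecotype, "attenuated", hypocotyl_multiplier=0.6),
        GenotypeSpec("mut-exaggerated", ecotype, "exaggerated", hypocotyl_multiplier=1.5),
        # inverse root: response multiplier large enough to flip the root
        # response above 1 (wild-type root response is below 1 under darkW)
        GenotypeSpec("mut-inverse", ecotype, "inverse",
                     hypocotyl_multiplier=0.7, root_multiplier=4.5),
        GenotypeSpec("mut-confused", ecotype, "confused", noise_inflation=2.5),
        GenotypeSpec("mut-perception", ecotype, "perception_null"),
    ]


# ---------------------------------------------------------------------------
# screen dataset


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Gaussian draws with non-positive values resampled (not truncated-renormalised)."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def _effective_multipliers(g: GenotypeSpec, base_resp_h: float, base_resp_r: float) -> tuple[float, float]:
    if g.response_class == "confused":
        # no adjustment to water withdrawal: organ responses pinned to 1
        return 1.0 / base_resp_h, 1.0 / base_resp_r
    return g.hypocotyl_multiplier, g.root_multiplier


def _group_params(g: GenotypeSpec, cond: ConditionSpec, conditions: dict[str, ConditionSpec]):
    """(mean, sd) per organ for one genotype in one condition.

    darkW means are shifted so the genotype's dark→darkW response equals
    multiplier × wild-type response; standard deviations scale with the mean
    (constant CV) and with noise_inflation.
    """
    base = cond
    if g.response_class == "perception_null" and cond.light_intensity > 0:
        dark_like = "darkW" if cond.water_potential < 0 else "dark"
        if dark_like in conditions:
            base = replace(conditions[dark_like],
                           hypocotyl_width_mean=cond.hypocotyl_width_mean,
                           hypocotyl_width_sd=cond.hypocotyl_width_sd)
    mu_h, sd_h = base.hypocotyl_mean, base.hypocotyl_sd
    mu_r, sd_r = base.root_mean, base.root_sd
    if cond.name == "darkW" and "dark" in conditions:
        dark = conditions["dark"]
        resp_h = dark.hypocotyl_mean / cond.hypocotyl_mean
        resp_r = dark.root_mean / cond.root_mean
        m_h, m_r = _effective_multipliers(g, resp_h, resp_r)
        mu_h = dark.hypocotyl_mean / (resp_h * m_h)
        mu_r = dark.root_mean / (resp_r * m_r)
        sd_h = cond.hypocotyl_sd * mu_h / cond.hypocotyl_mean
        sd_r = cond.root_sd * mu_r / cond.root_mean
    ni = g.noise_inflation
    return (mu_h, sd_h * ni), (mu_r, sd_r * ni), (cond.hypocotyl_width_mean, cond.hypocotyl_width_sd * ni)


def generate_screen_dataset(
    conditions: list[ConditionSpec] | dict[str, ConditionSpec],
    genotypes: list[GenotypeSpec],
    n_per_group: int,
    n_replicates: int = 3,
    n_plates: int = 2,
    seed: int = 0,
    plate_sd: float = 0.1,
) -> pd.DataFrame:
    """Simulate one screen: one row per seedling.

    Every genotype is sown on every plate of its replicate/condition batch
    (round-robin), so each mutant shares plates with its wild-type ecotype —
    the pairing the response-quotient normalisation relies on.  Plate effects
    are multiplicative log-normal (sd ``plate_sd``) per organ.
    """
    if n_per_group < 2:
        raise InputError(f"n_per_group must be >= 2, got {n_per_group}")
    if n_replicates < 1 or n_plates < 1:
        raise InputError("n_replicates and n_plates must be >= 1")
    if isinstance(conditions, dict):
        cond_map = dict(conditions)
    else:
        cond_map = {c.name: c for c in conditions}
        if len(cond_map) != len(conditions):
            raise ConfigurationError("condition names must be unique")
    ids = {g.genotype_id for g in genotypes}
    by_id = {g.genotype_id: g for g in genotypes}
    for g in genotypes:
        if g.ecotype_ref not in ids:
            raise ConfigurationError(f"{g.genotype_id}: unresolved ecotype_ref {g.ecotype_ref!r}")
        if by_id[g.ecotype_ref].response_class != "normal":
            raise ConfigurationError(
                f"{g.genotype_id}: ecotype_ref {g.ecotype_ref!r} must be a normal-class wild type")

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for r in range(1, n_replicates + 1):
        rep_id = f"rep{r}"
        for cond in cond_map.values():
            plates = []
            for p in range(1, n_plates + 1):
                plates.append(PlateEffect(
                    plate_id=f"{rep_id}-{cond.name}-p{p}",
                    scale_hypocotyl=float(rng.lognormal(0.0, plate_sd)),
                    scale_root=float(rng.lognormal(0.0, plate_sd)),
                ))
            for g in genotypes:
                (mu_h, sd_h), (mu_r, sd_r), (mu_w, sd_w) = _group_params(g, cond, cond_map)
                hyp = _draw_positive(rng, mu_h, sd_h, n_per_group)
                root = _draw_positive(rng, mu_r, sd_r, n_per_group)
                width = _draw_positive(rng, mu_w, sd_w, n_per_group)
                for i in range(n_per_group):
                    pe = plates[i % n_plates]
                    rows.append({
                        "genotype_id": g.genotype_id,
                        "ecotype_ref": g.ecotype_ref,
                        "plate_id": pe.plate_id,
                        "replicate_id": rep_id,
                        "condition": cond.name,
                        "hypocotyl_length_mm": hyp[i] * pe.scale_hypocotyl,
                        "root_length_mm": root[i] * pe.scale_root,
                        "hypocotyl_width_mm": width[i],
                    })
    return pd.DataFrame(rows, columns=ORGAN_COLUMNS)


# ---------------------------------------------------------------------------
# cell files


def _file_length(spec: CellFileSpec) -> int:
    n_elong = math.ceil(
        math.log(spec.mature_length_mean / spec.meristem_length_mean)
        / math.log(spec.elongation_rate))
    return spec.elongation_onset_index + n_elong + spec.n_mature_cells


def expected_length_profile(spec: CellFileSpec) -> np.ndarray:
    """Noise-free expected cell length at each 1-based index."""
    n = _file_length(spec)
    out = np.empty(n)
    for i in range(1, n + 1):
        if i <= spec.elongation_onset_index:
            out[i - 1] = spec.meristem_length_mean
        else:
            out[i - 1] = min(
                spec.meristem_length_mean * spec.elongation_rate ** (i - spec.elongation_onset_index),
                spec.mature_length_mean)
    return out


def generate_cell_files(
    spec_by_condition: dict[str, CellFileSpec],
    n_roots: int,
    seed: int = 0,
    genotype_id: str = "Col-0",
) -> list[CellFile]:
    """Simulate epidermal cell files ordered from the quiescent centre.

    Meristematic cells fluctuate around the meristem length (constant CV
    noise); past the elongation onset, lengths follow the geometric expected
    profile with the same relative noise until the mature-length plateau,
    where they are drawn from the mature distribution.  Widths are drawn from
    the condition's width distribution for all cells.
    """
    if not spec_by_condition:
        raise InputError("spec_by_condition must not be empty")
    if n_roots < 1:
        raise InputError("n_roots must be >= 1")
    rng = np.random.default_rng(seed)
    files: list[CellFile] = []
    for cond, spec in spec_by_condition.items():
        profile = expected_length_profile(spec)
        rel_sd = spec.meristem_length_sd / spec.meristem_length_mean
        for j in range(1, n_roots + 1):
            lengths = np.empty(len(profile))
            for i, mu in enumerate(profile):
                if mu >= spec.mature_length_mean:
                    lengths[i] = _draw_positive(rng, spec.mature_length_mean, spec.mature_length_sd, 1)[0]
                else:
                    lengths[i] = _draw_positive(rng, mu, mu * rel_sd, 1)[0]
            widths = _draw_positive(rng, spec.width_mean, spec.width_sd, len(profile))
            files.append(CellFile(f"{cond}-root{j:03d}", cond, genotype_id, lengths, widths))
    return files


def cell_files_to_frame(files: list[CellFile]) -> pd.DataFrame:
    """Long-format table with 1-based cell_index from the QC."""
    rows = []
    for f in files:
        for i, (ln, w) in enumerate(zip(f.lengths, f.widths), start=1):
            rows.append((f.root_id, f.condition, f.genotype_id, i, ln, w))
    return pd.DataFrame(rows, columns=CELLFILE_COLUMNS)


def frame_to_cell_files(df: pd.DataFrame) -> list[CellFile]:
    files = []
    for (root_id, cond, gid), grp in df.groupby(["root_id", "condition", "genotype_id"], sort=False):
        grp = grp.sort_values("cell_index")
        files.append(CellFile(str(root_id), str(cond), str(gid),
                              grp["length_um"].to_numpy(), grp["width_um"].to_numpy()))
    return files


# ---------------------------------------------------------------------------
# mitotic counts


def generate_mitotic_counts(
    mean_by_condition: dict[str, float],
    n_roots: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson counts of M-phase marker positive cells per root tip."""
    if n_roots < 1:
        raise InputError("n_roots must be >= 1")
    for cond, mean in mean_by_condition.items():
        if mean < 0:
            raise InputError(f"mean for {cond!r} must be >= 0, got {mean}")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, mean in mean_by_condition.items():
        counts = rng.poisson(mean, size=n_roots)
        for j, c in enumerate(counts, start=1):
            rows.append((cond, f"{cond}-root{j:03d}", int(c)))
    return pd.DataFrame(rows, columns=["condition", "root_id", "count"])
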