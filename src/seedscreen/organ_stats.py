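"""Organ-level response statistics for the hypocotyl/root trade-off screen.

The central quantities:

* organ response = mean organ length in the dark / mean length under darkW;
* ratio adjustment = (hypocotyl/root) in the dark ÷ (hypocotyl/root) under
  darkW, quantifying how far the trade-off shifted;
* response quotient RQ = mutant response / same-plate wild-type response,
  so RQ = 1 means wild-type-like.

Responses are ratios of group means, not means of per-seedling ratios:
seedlings are destructively measured in one condition each, so a
per-seedling dark/darkW response does not exist.  Significance comes from a
test-selection cascade (Shapiro–Wilk normality gate, then Levene's
equal-variance gate choosing Student vs Welch, falling back to
Mann–Whitney-U), and multiple testing across a declared comparison family
uses Benjamini–Hochberg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ComputationError, InputError, PairingError

__all__ = [
    "ReplicateSummary",
    "GenotypeSummary",
    "organ_response",
    "ratio_adjustment",
    "rq_normalize",
    "compare_groups",
    "bh_adjust",
    "summarize_replicate",
    "summarize_screen",
    "aggregate_genotype",
    "hypocotyl_volume",
    "anisotropy",
    "contribution_table",
]


@dataclass
class ReplicateSummary:
    genotype_id: str
    replicate_id: str
    response_hypocotyl: float
    response_root: float
    ratio_adjustment: float
    rq_hypocotyl: float
    rq_root: float
    rq_ratio: float
    p_hypocotyl: float
    p_root: float
    p_ratio: float
    n_dark: int
    n_darkW: int
    test_hypocotyl: str = ""
    test_root: str = ""
    test_ratio: str = ""


@dataclass
class GenotypeSummary:
    genotype_id: str
    mean_rq_hypocotyl: float
    mean_rq_root: float
    mean_rq_ratio: float
    median_p_hypocotyl: float
    median_p_root: float
    median_p_ratio: float
    n_replicates: int

    @property
    def replication(self) -> str:
        """'sufficient' once at least three biological replicates back the means."""
        return "sufficient" if self.n_replicates >= 3 else "insufficient"


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise InputError(f"{name}: empty sample")
    return arr


def organ_response(lengths_dark, lengths_darkW) -> float:
    """Mean organ length in the dark over mean length under darkW."""
    d = _as_sample(lengths_dark, "lengths_dark")
    w = _as_sample(lengths_darkW, "lengths_darkW")
    denom = w.mean()
    if denom == 0 or d.mean() == 0:
        raise ComputationError("organ response undefined for zero mean length")
    return float(d.mean() / denom)


def ratio_adjustment(hyp_dark, root_dark, hyp_darkW, root_darkW) -> float:
    """(hypocotyl/root) in the dark divided by (hypocotyl/root) under darkW."""
    return organ_response(hyp_dark, hyp_darkW) / organ_response(root_dark, root_darkW)


def rq_normalize(mutant_value: float, wildtype_value: float) -> float:
    """Response quotient: mutant response over same-plate wild-type response."""
    if wildtype_value <= 0:
        raise ComputationError(f"wild-type value must be > 0, got {wildtype_value}")
    return float(mutant_value) / float(wildtype_value)


def compare_groups(
    a,
    b,
    alpha_normality: float = 0.05,
    alpha_variance: float = 0.05,
) -> tuple[float, str]:
    """Two-sided comparison with automated test selection.

    Cascade: Shapiro–Wilk on each group; if either rejects normality the
    comparison falls back to the Mann–Whitney-U test.  Otherwise Levene's
    test decides between Student's (equal variances) and Welch's t-test.
    Returns ``(p_value, test_used)`` with test_used in
    {"student", "welch", "mannwhitney"}.

    Two identical constant samples are incomparable by any of these tests
    and return p = 1 with a warning.
    """
    x = _as_sample(a, "a")
    y = _as_sample(b, "b")
    if x.size < 3 or y.size < 3:
        raise InputError("compare_groups needs >= 3 values per group")
    x_const = np.ptp(x) == 0
    y_const = np.ptp(y) == 0
    if x_const and y_const and x[0] == y[0]:
        warnings.warn("both samples constant and identical; p-value set to 1", stacklevel=2)
        return 1.0, "degenerate"
    if x_const or y_const:
        # Shapiro-Wilk is undefined for constant data; treat as non-normal
        p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        return float(p), "mannwhitney"
    if (stats.shapiro(x).pvalue < alpha_normality
            or stats.shapiro(y).pvalue < alpha_normality):
        p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        return float(p), "mannwhitney"
    equal_var = stats.levene(x, y).pvalue >= alpha_variance
    p = stats.ttest_ind(x, y, equal_var=equal_var).pvalue
    return float(p), ("student" if equal_var else "welch")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypocotyl_volume(width: float, length: float, cylindrical_radius: bool = False) -> float:
    """Hypocotyl volume assuming a cylindrical organ, V = πWL (as published).

    The published formula multiplies width and length directly; the
    dimensionally conventional cylinder volume π(W/2)²L is available with
    ``cylindrical_radius=True`` but is off by default to match the source
    convention.
    """
    if width <= 0 or length <= 0:
        raise InputError("width and length must be > 0")
    if cylindrical_radius:
        return math.pi * (width / 2.0) ** 2 * length
    return math.pi * width * length


def anisotropy(length: float, width: float) -> float:
    """2D cell anisotropy, length/width; 1 for isodiametric cells."""
    if width <= 0:
        raise ComputationError("width must be > 0")
    return float(length) / float(width)


# ---------------------------------------------------------------------------
# replicate- and genotype-level summaries


def _condition_slices(records: pd.DataFrame, genotype: str, dark: str, darkW: str):
    g = records[records["genotype_id"] == genotype]
    d = g[g["condition"] == dark]
    w = g[g["condition"] == darkW]
    return d, w


def _replicate_summary_one(
    records: pd.DataFrame, genotype: str, dark: str, darkW: str, replicate_id: str
) -> tuple[ReplicateSummary, float, float, float]:
    d, w = _condition_slices(records, genotype, dark, darkW)
    resp_h = organ_response(d["hypocotyl_length_mm"], w["hypocotyl_length_mm"])
    resp_r = organ_response(d["root_length_mm"], w["root_length_mm"])
    adj = resp_h / resp_r
    p_h, t_h = compare_groups(d["hypocotyl_length_mm"], w["hypocotyl_length_mm"])
    p_r, t_r = compare_groups(d["root_length_mm"], w["root_length_mm"])
    ratios_d = d["hypocotyl_length_mm"] / d["root_length_mm"]
    ratios_w = w["hypocotyl_length_mm"] / w["root_length_mm"]
    p_q, t_q = compare_groups(ratios_d, ratios_w)
    summ = ReplicateSummary(
        genotype_id=genotype, replicate_id=replicate_id,
        response_hypocotyl=resp_h, response_root=resp_r, ratio_adjustment=adj,
        rq_hypocotyl=np.nan, rq_root=np.nan, rq_ratio=np.nan,
        p_hypocotyl=p_h, p_root=p_r, p_ratio=p_q,
        n_dark=len(d), n_darkW=len(w),
        test_hypocotyl=t_h, test_root=t_r, test_ratio=t_q,
    )
    return summ, resp_h, resp_r, adj


def summarize_replicate(
    records: pd.DataFrame,
    mutant: str,
    wildtype: str,
    dark: str = "dark",
    darkW: str = "darkW",
    replicate_id: str | None = None,
) -> tuple[ReplicateSummary, ReplicateSummary]:
    """Summarise one biological replicate for a mutant and its paired wild type.

    ``records`` must hold one replicate's seedling rows for both genotypes in
    both conditions, with the two genotypes sharing plates (the normalisation
    assumes same-plate pairing; missing pairings raise :class:`PairingError`).
    Returns ``(mutant_summary, wildtype_summary)``; the wild type's RQs are
    exactly 1 by construction.
    """
    required = {"genotype_id", "plate_id", "condition", "hypocotyl_length_mm", "root_length_mm"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise InputError(f"records missing columns: {sorted(missing_cols)}")
    if replicate_id is None:
        reps = records.get("replicate_id")
        replicate_id = str(reps.iloc[0]) if reps is not None and len(reps) else "rep?"

    missing = []
    for g in (mutant, wildtype):
        for c in (dark, darkW):
            sub = records[(records["genotype_id"] == g) & (records["condition"] == c)]
            if sub.empty:
                missing.append((g, c))
            elif len(sub) < 3:
                raise InputError(f"group ({g}, {c}) has {len(sub)} seedlings; need >= 3")
    if missing:
        raise PairingError(f"missing genotype/condition cells: {missing}", missing=missing)
    for c in (dark, darkW):
        mut_plates = set(records.loc[(records["genotype_id"] == mutant)
                                     & (records["condition"] == c), "plate_id"])
        wt_plates = set(records.loc[(records["genotype_id"] == wildtype)
                                    & (records["condition"] == c), "plate_id"])
        unmatched = mut_plates - wt_plates
        if unmatched:
            raise PairingError(
                f"mutant plates without wild-type cohort in {c}: {sorted(unmatched)}",
                missing=sorted(unmatched))

    wt_summ, wt_resp_h, wt_resp_r, wt_adj = _replicate_summary_one(
        records, wildtype, dark, darkW, replicate_id)
    mu_summ, mu_resp_h, mu_resp_r, mu_adj = _replicate_summary_one(
        records, mutant, dark, darkW, replicate_id)
    mu_summ.rq_hypocotyl = rq_normalize(mu_resp_h, wt_resp_h)
    mu_summ.rq_root = rq_normalize(mu_resp_r, wt_resp_r)
    mu_summ.rq_ratio = rq_normalize(mu_adj, wt_adj)
    wt_summ.rq_hypocotyl = rq_normalize(wt_resp_h, wt_resp_h)
    wt_summ.rq_root = rq_normalize(wt_resp_r, wt_resp_r)
    wt_summ.rq_ratio = rq_normalize(wt_adj, wt_adj)
    return mu_summ, wt_summ


def summarize_screen(
    records: pd.DataFrame,
    dark: str = "dark",
    darkW: str = "darkW",
) -> list[ReplicateSummary]:
    """Per-replicate summaries for every genotype in a screen table."""
    out: list[ReplicateSummary] = []
    pairs = records[["genotype_id", "ecotype_ref"]].drop_duplicates()
    for rep_id, rep in records.groupby("replicate_id", sort=False):
        for _, (gid, ref) in pairs.iterrows():
            mu, wt = summarize_replicate(rep, gid, ref, dark, darkW, replicate_id=str(rep_id))
            out.append(mu if gid != ref else wt)
    return out


def _median(values: list[float]) -> float:
    """Median; for an even count, the mean of the two central values."""
    return float(np.median(np.asarray(values, dtype=float)))


def aggregate_genotype(summaries: list[ReplicateSummary]) -> GenotypeSummary:
    """Mean RQs and median P-values over a genotype's biological replicates."""
    if not summaries:
        raise InputError("aggregate_genotype needs at least one replicate summary")
    ids = {s.genotype_id for s in summaries}
    if len(ids) > 1:
        raise InputError(f"summaries mix genotypes: {sorted(ids)}")
    return GenotypeSummary(
        genotype_id=summaries[0].genotype_id,
        mean_rq_hypocotyl=float(np.mean([s.rq_hypocotyl for s in summaries])),
        mean_rq_root=float(np.mean([s.rq_root for s in summaries])),
        mean_rq_ratio=float(np.mean([s.rq_ratio for s in summaries])),
        median_p_hypocotyl=_median([s.p_hypocotyl for s in summaries]),
        median_p_root=_median([s.p_root for s in summaries]),
        median_p_ratio=_median([s.p_ratio for s in summaries]),
        n_replicates=len(summaries),
    )


# ---------------------------------------------------------------------------
# fold-change decomposition (organ vs cell geometry)

_FC_PAIRS = {  # cell variable -> matching organ variable
    "cell_length": "organ_length",
    "cell_width": "organ_width",
}


def contribution_table(records: pd.DataFrame, reference_condition: str = "light") -> pd.DataFrame:
    """Fold-changes of organ and cell geometry against a reference condition.

    Expects columns ``condition`` plus any of ``organ_length``,
    ``organ_width``, ``cell_length``, ``cell_width`` (long per-measurement
    rows; NaNs ignored).  FC(variable, condition) = mean(condition) /
    mean(reference).  For matched cell/organ pairs the cellular contribution
    is reported as 100 · FC_cell / FC_organ — the share of the organ-level
    fold-change that cell geometry accounts for (it can exceed 100% when the
    cellular change overshoots the organ change).
    """
    if "condition" not in records.columns:
        raise InputError("records need a 'condition' column")
    conds = list(pd.unique(records["condition"]))
    if reference_condition not in conds:
        raise InputError(f"reference condition {reference_condition!r} absent from records")
    variables = [v for v in ("organ_length", "organ_width", "cell_length", "cell_width")
                 if v in records.columns]
    if not variables:
        raise InputError("no measurement columns found")
    means = {(v, c): records.loc[records["condition"] == c, v].dropna().mean()
             for v in variables for c in conds}
    rows = []
    for v in variables:
        ref = means[(v, reference_condition)]
        if not np.isfinite(ref) or ref <= 0:
            raise ComputationError(f"reference mean for {v} not positive")
        for c in conds:
            fc = means[(v, c)] / ref
            contribution = np.nan
            organ_var = _FC_PAIRS.get(v)
            if organ_var in variables:
                fc_organ = means[(organ_var, c)] / means[(organ_var, reference_condition)]
                contribution = 100.0 * fc / fc_organ
            rows.append({
                "variable": v,
                "condition": c,
                "reference_condition": reference_condition,
                "fc": float(fc),
                "contribution_pct": float(contribution) if np.isfinite(contribution) else np.nan,
            })
    return pd.DataFrame(rows)
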