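"""Classification of genotype responses and decision-mutant calls.

A screen readout is classified twice: by effect size (response quotient
against printed boundaries 0.8 and 1.2) and by significance (median
response P-value against 0.05 and 1e-5).  A genotype is "confused" when its
ratio quotient is attenuated while its ratio P-value is weak — the lower-left
quadrant of the RQ-vs-P volcano plot.  A decision mutant must additionally
fail on all three screen criteria: ratio failure (attenuated ratio RQ or an
inverse organ response), weak significance, and one organ exceeding
wild-type length under combined stress.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .organ_stats import GenotypeSummary, compare_groups, organ_response

__all__ = [
    "RQ_ATTENUATED", "RQ_EXAGGERATED", "P_INSIGNIFICANT", "P_ATTENUATED",
    "DecisionCall", "classify_rq", "classify_p", "volcano_coords",
    "confused_call", "organ_exceedance", "response_direction",
    "decision_mutant_call", "classify_screen",
]

RQ_ATTENUATED = 0.8  # below: attenuated; 0.8–1.2 inclusive: normal
RQ_EXAGGERATED = 1.2  # above: exaggerated
P_INSIGNIFICANT = 0.05  # at or above: insignificant
P_ATTENUATED = 0.00001  # in [1e-5, 0.05): attenuated significance

P_FLOOR = 1e-300  # volcano clipping floor for P = 0


@dataclass
class DecisionCall:
    genotype_id: str
    rq_label: str
    p_label: str
    direction_hypocotyl: str
    direction_root: str
    confused: bool
    decision_mutant: bool
    criteria_met: set = field(default_factory=set)


def classify_rq(rq: float) -> str:
    """Effect-size label; boundaries 0.8 and 1.2 are inclusive on the normal side."""
    if not rq > 0:
        raise InputError(f"RQ must be > 0, got {rq}")
    if rq < RQ_ATTENUATED:
        return "attenuated"
    if rq > RQ_EXAGGERATED:
        return "exaggerated"
    return "normal"


def classify_p(p: float) -> str:
    """Significance label for a (median) response P-value."""
    if not (0 <= p <= 1):
        raise InputError(f"P-value must lie in [0, 1], got {p}")
    if p >= P_INSIGNIFICANT:
        return "insignificant"
    if p >= P_ATTENUATED:
        return "attenuated_significance"
    return "significant"


def volcano_coords(summary: GenotypeSummary, readout: str = "ratio",
                   p_floor: float = P_FLOOR) -> tuple[float, float]:
    """(mean RQ, −log10 median P) for one genotype and readout."""
    rq = getattr(summary, f"mean_rq_{readout}")
    p = getattr(summary, f"median_p_{readout}")
    if p <= 0:
        warnings.warn(f"median P for {summary.genotype_id} clipped to {p_floor}", stacklevel=2)
        p = p_floor
    return float(rq), -math.log10(p)


def confused_call(summary: GenotypeSummary) -> bool:
    """Lower-left volcano quadrant: attenuated ratio RQ with weak P.

    The P boundary is the attenuated-significance threshold 1e-5, not 0.05:
    genotypes with P as small as a few millis still sit in the confused
    quadrant provided their ratio quotient is attenuated.
    """
    rq = summary.mean_rq_ratio
    p = summary.median_p_ratio
    if not np.isfinite(rq) or not np.isfinite(p):
        raise InputError(f"{summary.genotype_id}: ratio readout incomplete")
    return rq < RQ_ATTENUATED and p >= P_ATTENUATED


_ORGAN_COL = {"hypocotyl": "hypocotyl_length_mm", "root": "root_length_mm"}


def organ_exceedance(
    mutant_records: pd.DataFrame,
    wildtype_records: pd.DataFrame,
    condition: str = "darkW",
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Per organ: does the mutant significantly exceed wild-type length?"""
    out = {}
    for organ, col in _ORGAN_COL.items():
        m = mutant_records.loc[mutant_records["condition"] == condition, col]
        w = wildtype_records.loc[wildtype_records["condition"] == condition, col]
        if m.empty or w.empty:
            raise InputError(f"empty group for organ exceedance in {condition!r}")
        if m.mean() <= w.mean():
            out[organ] = False
            continue
        p, _ = compare_groups(m, w)
        out[organ] = bool(p < alpha)
    return out


def response_direction(
    mutant_records: pd.DataFrame,
    wildtype_records: pd.DataFrame,
    organ: str,
    dark: str = "dark",
    darkW: str = "darkW",
    alpha: float = 0.05,
) -> str:
    """'inverse' when both genotypes respond significantly but on opposite
    sides of 1; 'wild-type-like' otherwise."""
    col = _ORGAN_COL[organ]
    responses, ps = [], []
    for rec in (mutant_records, wildtype_records):
        d = rec.loc[rec["condition"] == dark, col]
        w = rec.loc[rec["condition"] == darkW, col]
        if d.empty or w.empty:
            raise InputError(f"missing {organ} data for direction call")
        responses.append(organ_response(d, w))
        ps.append(compare_groups(d, w)[0])
    both_significant = ps[0] < alpha and ps[1] < alpha
    opposite = (responses[0] - 1.0) * (responses[1] - 1.0) < 0
    return "inverse" if (both_significant and opposite) else "wild-type-like"


def decision_mutant_call(
    summary: GenotypeSummary,
    exceedance: dict[str, bool],
    directions: dict[str, str],
) -> DecisionCall:
    """Assemble the three-criterion decision-mutant call for one genotype.

    (i) ratio_failure — attenuated ratio quotient or an inverse organ
    response; (ii) weak_significance — ratio P insignificant or only
    attenuated in significance; (iii) organ_exceedance — at least one organ
    significantly longer than wild type under combined stress.  A decision
    mutant meets all three.
    """
    rq_label = classify_rq(summary.mean_rq_ratio)
    p_label = classify_p(summary.median_p_ratio)
    criteria: set[str] = set()
    if rq_label == "attenuated" or "inverse" in directions.values():
        criteria.add("ratio_failure")
    if p_label in ("insignificant", "attenuated_significance"):
        criteria.add("weak_significance")
    if any(exceedance.values()):
        criteria.add("organ_exceedance")
    return DecisionCall(
        genotype_id=summary.genotype_id,
        rq_label=rq_label,
        p_label=p_label,
        direction_hypocotyl=directions.get("hypocotyl", "wild-type-like"),
        direction_root=directions.get("root", "wild-type-like"),
        confused=confused_call(summary),
        decision_mutant=criteria == {"ratio_failure", "weak_significance", "organ_exceedance"},
        criteria_met=criteria,
    )


def classify_screen(
    records: pd.DataFrame,
    summaries: dict[str, GenotypeSummary],
    dark: str = "dark",
    darkW: str = "darkW",
) -> pd.DataFrame:
    """Decision calls for every genotype of a screen table.

    ``summaries`` maps genotype_id to its aggregated :class:`GenotypeSummary`.
    Exceedance and direction are computed on the pooled seedling records
    against each genotype's wild-type ecotype.  Wild types (their own
    reference) are classified too, serving as negative controls.
    """
    rows = []
    pairs = records[["genotype_id", "ecotype_ref"]].drop_duplicates()
    for _, (gid, ref) in pairs.iterrows():
        if gid not in summaries:
            raise InputError(f"no aggregated summary for genotype {gid!r}")
        mut = records[records["genotype_id"] == gid]
        wt = records[records["genotype_id"] == ref]
        exc = organ_exceedance(mut, wt, condition=darkW)
        dirs = {organ: response_direction(mut, wt, organ, dark, darkW)
                for organ in ("hypocotyl", "root")}
        call = decision_mutant_call(summaries[gid], exc, dirs)
        x, y = volcano_coords(summaries[gid])
        rows.append({
            "genotype_id": gid,
            "ecotype_ref": ref,
            "mean_rq_ratio": summaries[gid].mean_rq_ratio,
            "median_p_ratio": summaries[gid].median_p_ratio,
            "volcano_x": x,
            "volcano_y": y,
            "rq_label": call.rq_label,
            "p_label": call.p_label,
            "direction_hypocotyl": call.direction_hypocotyl,
            "direction_root": call.direction_root,
            "exceed_hypocotyl": exc["hypocotyl"],
            "exceed_root": exc["root"],
            "confused": call.confused,
            "decision_mutant": call.decision_mutant,
            "criteria_met": ";".join(sorted(call.criteria_met)),
        })
    return pd.DataFrame(rows)


def volcano_plot(calls: pd.DataFrame, path: str, readout: str = "ratio") -> None:
    """Write a volcano plot (RQ vs −log10 P) with the screen's guide lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = calls["confused"].map({True: "tab:red", False: "tab:gray"})
    ax.scatter(calls["volcano_x"], calls["volcano_y"], c=colors, s=25)
    for _, row in calls.iterrows():
        ax.annotate(row["genotype_id"], (row["volcano_x"], row["volcano_y"]),
                    fontsize=6, xytext=(2, 2), textcoords="offset points")
    ax.axvline(RQ_ATTENUATED, ls="--", lw=0.8, c="k")
    ax.axvline(RQ_EXAGGERATED, ls="--", lw=0.8, c="k")
    ax.axhline(-math.log10(P_INSIGNIFICANT), ls=":", lw=0.8, c="k")
    ax.axhline(-math.log10(P_ATTENUATED), ls=":", lw=0.8, c="k")
    ax.set_xlabel(f"mean RQ ({readout})")
    ax.set_ylabel("-log10 median P")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
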