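"""Root apical meristem zonation from epidermal cell files.

Cell lengths along a file from the quiescent centre (QC) fall into two
populations — short meristematic cells and long elongating cells — modelled
as a two-component Gaussian mixture fitted by expectation maximisation.
Cells with posterior probability > 0.8 of belonging to the short component
are called meristematic.  Complementary rule-based counts are provided:
isodiametric cells (length ≤ width, contiguous run from the QC) and
transition cells (from the first longer-than-wide cell while each cell stays
under 150% of its predecessor's length).  Positional curves of length,
width or anisotropy against cell number from the QC are smoothed with a
tricube-weighted local polynomial regression (the 'loess' method) with
bootstrap confidence bands over roots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputError, NotFoundSignal
from .organ_stats import bh_adjust
from .synthgen import CellFile

__all__ = [
    "GmmFit", "ZonationResult", "SmoothedCurve",
    "fit_two_gaussian_em", "posterior_short", "classify_meristematic",
    "count_isodiametric", "count_transition", "mature_cell_length",
    "first_elongated_length", "mitotic_summary", "positional_curve",
    "analyze_zonation",
]

VARIANCE_FLOOR = 1e-6  # µm²; E-step degenerates below this
TRANSITION_FACTOR = 1.5


@dataclass
class GmmFit:
    """Two-Gaussian mixture over cell lengths; 'short' is the smaller-mean component."""

    mu_short: float
    mu_long: float
    sigma_short: float
    sigma_long: float
    weight_short: float
    posterior_short: np.ndarray
    log_likelihood_trace: np.ndarray
    converged: bool
    n_iterations: int
    degenerate: bool = False


@dataclass
class ZonationResult:
    root_id: str
    condition: str
    meristem_cell_count_gmm: int  # all cells with short-posterior > threshold
    meristem_run_from_qc: int  # contiguous meristematic run starting at the QC
    meristem_length_sum_um: float
    isodiametric_count: int
    transition_count: int
    first_elongated_length: float  # µm; NaN when every cell is meristematic
    labels: np.ndarray = field(repr=False, default=None)  # True = meristematic


@dataclass
class SmoothedCurve:
    variable: str
    grid: np.ndarray
    fit: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    max_slope: float
    max_slope_index: int
    span: float


def _loglik(x: np.ndarray, w: float, mu1: float, s1: float, mu2: float, s2: float) -> float:
    pdf = w * stats.norm.pdf(x, mu1, s1) + (1 - w) * stats.norm.pdf(x, mu2, s2)
    return float(np.sum(np.log(np.maximum(pdf, 1e-300))))


def fit_two_gaussian_em(
    lengths,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
    n_restarts: int = 0,
) -> GmmFit:
    """Fit a two-Gaussian mixture to cell lengths by EM.

    Deterministic initialisation splits the sorted sample at its median and
    seeds each component from one half; ``n_restarts`` > 0 adds seeded random
    initialisations and keeps the best final log-likelihood.  Convergence is
    a relative log-likelihood change below ``tol``; variances are floored at
    ``VARIANCE_FLOOR`` and a fit that hits the floor is flagged degenerate.
    The returned trace is monotone non-decreasing (a guarantee of EM).
    """
    x = np.asarray(lengths, dtype=float).ravel()
    if x.size < 10:
        raise InputError(f"need >= 10 cell lengths, got {x.size}")
    if np.unique(x).size < 2:
        raise InputError("need at least 2 distinct lengths")

    def _run(mu1, s1, mu2, s2, w):
        trace = []
        degenerate = False
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E step
            p1 = w * stats.norm.pdf(x, mu1, s1)
            p2 = (1 - w) * stats.norm.pdf(x, mu2, s2)
            total = p1 + p2
            total[total == 0] = 1e-300
            r1 = p1 / total
            # M step
            n1 = r1.sum()
            n2 = x.size - n1
            if n1 < 1e-12 or n2 < 1e-12:
                degenerate = True
                break
            mu1 = float((r1 * x).sum() / n1)
            mu2 = float(((1 - r1) * x).sum() / n2)
            v1 = float((r1 * (x - mu1) ** 2).sum() / n1)
            v2 = float(((1 - r1) * (x - mu2) ** 2).sum() / n2)
            if v1 < VARIANCE_FLOOR or v2 < VARIANCE_FLOOR:
                degenerate = True
            s1 = math.sqrt(max(v1, VARIANCE_FLOOR))
            s2 = math.sqrt(max(v2, VARIANCE_FLOOR))
            w = float(n1 / x.size)
            ll = _loglik(x, w, mu1, s1, mu2, s2)
            trace.append(ll)
            if len(trace) >= 2:
                prev = trace[-2]
                if abs(ll - prev) <= tol * max(abs(prev), 1.0):
                    converged = True
                    break
        return mu1, s1, mu2, s2, w, np.asarray(trace), converged, it, degenerate

    sx = np.sort(x)
    half = x.size // 2
    lo, hi = sx[:half], sx[half:]
    inits = [(float(lo.mean()), max(float(lo.std()), 1e-3),
              float(hi.mean()), max(float(hi.std()), 1e-3), 0.5)]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            mus = rng.choice(x, size=2, replace=False)
            s = max(float(x.std()) / 2, 1e-3)
            inits.append((float(mus.min()), s, float(mus.max()), s, 0.5))

    best = None
    for init in inits:
        res = _run(*init)
        if best is None or (len(res[5]) and res[5][-1] > best[5][-1]):
            best = res
    mu1, s1, mu2, s2, w, trace, converged, n_iter, degenerate = best
    if degenerate:
        warnings.warn("degenerate mixture fit: a component variance hit the floor", stacklevel=2)
    # fix component identity by mean order
    if mu1 > mu2:
        mu1, mu2, s1, s2, w = mu2, mu1, s2, s1, 1 - w
    post = posterior_short(x, mu1, s1, mu2, s2, w)
    return GmmFit(mu1, mu2, s1, s2, w, post, trace, converged, n_iter, degenerate)


def posterior_short(x, mu_short, sigma_short, mu_long, sigma_long, weight_short) -> np.ndarray:
    """Posterior probability of the short-length component for each value."""
    x = np.asarray(x, dtype=float)
    p1 = weight_short * stats.norm.pdf(x, mu_short, sigma_short)
    p2 = (1 - weight_short) * stats.norm.pdf(x, mu_long, sigma_long)
    total = p1 + p2
    total[total == 0] = 1e-300
    return p1 / total


def classify_meristematic(fit: GmmFit, threshold: float = 0.8,
                          lengths=None) -> np.ndarray:
    """Boolean per cell: posterior of the short component strictly above threshold.

    With ``lengths`` given, posteriors are evaluated for those values under
    the fitted mixture (e.g. labelling a single root against a pooled
    per-condition fit); otherwise the fit's own training posteriors are used.
    """
    if not (0 < threshold < 1):
        raise InputError(f"threshold must lie in (0, 1), got {threshold}")
    if lengths is None:
        post = fit.posterior_short
    else:
        post = posterior_short(lengths, fit.mu_short, fit.sigma_short,
                               fit.mu_long, fit.sigma_long, fit.weight_short)
    return post > threshold


def count_isodiametric(file: CellFile) -> int:
    """Cells in the initial run from the QC with length ≤ width."""
    n = 0
    for ln, w in zip(file.lengths, file.widths):
        if ln > w:
            break
        n += 1
    return n


def count_transition(file: CellFile) -> int:
    """Transition-zone cells: from the first longer-than-wide cell, extend
    while each next cell's length stays under 150% of its predecessor's."""
    start = None
    for i, (ln, w) in enumerate(zip(file.lengths, file.widths)):
        if ln > w:
            start = i
            break
    if start is None:
        return 0
    n = 1
    for i in range(start + 1, len(file)):
        if file.lengths[i] >= TRANSITION_FACTOR * file.lengths[i - 1]:
            break
        n += 1
    return n


def mature_cell_length(lengths, k: int = 10) -> float:
    """Mean of the k most elongated cells (pooled per condition)."""
    x = np.asarray(lengths, dtype=float).ravel()
    if k < 1:
        raise InputError("k must be >= 1")
    if x.size < k:
        raise InputError(f"need >= {k} cells, got {x.size}")
    return float(np.sort(x)[-k:].mean())


def first_elongated_length(file: CellFile, labels) -> float:
    """Length of the lowest-index cell labelled elongating (non-meristematic)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != file.lengths.shape:
        raise InputError("labels must align with the cell file")
    elong = np.nonzero(~labels)[0]
    if elong.size == 0:
        raise NotFoundSignal(f"{file.root_id}: every cell is meristematic")
    return float(file.lengths[elong[0]])


def mitotic_summary(
    counts_by_condition: dict,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Mean mitotic-marker counts per condition and pairwise fold-changes.

    Fold-change A/B = mean(A)/mean(B); a zero-mean denominator yields NaN
    with a warning.  Pairs are compared with two-sided Mann–Whitney-U and
    Benjamini–Hochberg adjusted across the requested family.
    """
    if not counts_by_condition:
        raise InputError("counts_by_condition must not be empty")
    arrays = {}
    for cond, counts in counts_by_condition.items():
        arr = np.asarray(counts, dtype=float).ravel()
        if arr.size == 0:
            raise InputError(f"condition {cond!r} has no roots")
        arrays[cond] = arr
    means = {c: float(a.mean()) for c, a in arrays.items()}
    if pairs is None:
        conds = list(arrays)
        pairs = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1:]]
    rows, ps = [], []
    for a, b in pairs:
        if means[b] == 0:
            warnings.warn(f"fold-change {a}/{b} undefined (zero-mean denominator)", stacklevel=2)
            fc = np.nan
        else:
            fc = means[a] / means[b]
        if np.ptp(arrays[a]) == 0 and np.ptp(arrays[b]) == 0 and arrays[a][0] == arrays[b][0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided").pvalue)
        rows.append({"condition_a": a, "condition_b": b, "fold_change": fc, "p_value": p})
        ps.append(p)
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(ps)
    return means, table


# ---------------------------------------------------------------------------
# positional smoothing (loess-style)


def _local_polyfit(xs: np.ndarray, ys: np.ndarray, x0: float, span: float, degree: int):
    """Tricube-weighted polynomial fit around x0 evaluated at x0."""
    n = xs.size
    k = max(int(math.ceil(span * n)), degree + 2)
    k = min(k, n)
    d = np.abs(xs - x0)
    order = np.argsort(d, kind="stable")[:k]
    while np.unique(xs[order]).size <= degree and k < n:
        k = min(n, k * 2)
        order = np.argsort(d, kind="stable")[:k]
    xw, yw = xs[order], ys[order]
    h = d[order].max()
    if h == 0:
        return float(yw.mean())
    w = np.clip(1 - (d[order] / h) ** 3, 0, None) ** 3
    w[w <= 0] = 1e-12
    coeffs = np.polynomial.polynomial.polyfit(xw - x0, yw, degree, w=np.sqrt(w))
    return float(coeffs[0])


def _curve_on_grid(xs, ys, grid, span, degree):
    return np.array([_local_polyfit(xs, ys, x0, span, degree) for x0 in grid])


def positional_curve(
    files: list[CellFile],
    variable: str = "length",
    span: float = 0.75,
    degree: int = 2,
    ci: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
) -> SmoothedCurve:
    """Smoothed positional profile of a cell variable against index from the QC.

    Measurements from all files are pooled as (cell index, value) points and
    smoothed with tricube-weighted local polynomial regression on the integer
    index grid.  The confidence band is a seeded bootstrap over whole roots
    (the experimental resampling unit).  The maximum fitted slope and its
    index are reported — the "steep slope" of the elongation onset.
    """
    if len(files) < 2:
        raise InputError("need at least 2 cell files")
    if not (0 < span <= 1):
        raise InputError("span must lie in (0, 1]")
    if degree not in (1, 2):
        raise InputError("degree must be 1 or 2")
    if not (0 < ci < 1):
        raise InputError("ci must lie in (0, 1)")

    def values(f: CellFile) -> np.ndarray:
        if variable == "length":
            return f.lengths
        if variable == "width":
            return f.widths
        if variable == "anisotropy":
            return f.lengths / f.widths
        raise InputError(f"unknown variable {variable!r}")

    xs = np.concatenate([np.arange(1, len(f) + 1, dtype=float) for f in files])
    ys = np.concatenate([values(f) for f in files])
    grid = np.arange(1, int(xs.max()) + 1, dtype=float)
    fit = _curve_on_grid(xs, ys, grid, span, degree)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        idx = rng.integers(0, len(files), size=len(files))
        bx = np.concatenate([np.arange(1, len(files[i]) + 1, dtype=float) for i in idx])
        by = np.concatenate([values(files[i]) for i in idx])
        boot[b] = _curve_on_grid(bx, by, grid, span, degree)
    alpha = (1 - ci) / 2
    lower = np.quantile(boot, alpha, axis=0)
    upper = np.quantile(boot, 1 - alpha, axis=0)

    slopes = np.gradient(fit, grid)
    imax = int(np.argmax(slopes))
    return SmoothedCurve(variable, grid, fit, lower, upper,
                         float(slopes[imax]), int(grid[imax]), span)


# ---------------------------------------------------------------------------
# per-root zonation driver


def analyze_zonation(
    files: list[CellFile],
    threshold: float = 0.8,
    pooled: bool = True,
    k_mature: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[list[ZonationResult], dict[str, GmmFit]]:
    """Zonation metrics for every root, with mixtures fitted per condition.

    By default cell lengths are pooled within each condition for the mixture
    fit (per-root fits via ``pooled=False`` need long files).  Returns the
    per-root results and the per-condition (or per-root) fits.
    """
    if not files:
        raise InputError("no cell files given")
    results: list[ZonationResult] = []
    fits: dict[str, GmmFit] = {}
    if pooled:
        for cond in {f.condition for f in files}:
            pool = np.concatenate([f.lengths for f in files if f.condition == cond])
            fits[cond] = fit_two_gaussian_em(pool, tol=tol, max_iter=max_iter)
    for f in files:
        fit = fits[f.condition] if pooled else fits.setdefault(
            f.root_id, fit_two_gaussian_em(f.lengths, tol=tol, max_iter=max_iter))
        labels = classify_meristematic(fit, threshold, lengths=f.lengths)
        run = 0
        for m in labels:
            if not m:
                break
            run += 1
        try:
            first_len = first_elongated_length(f, labels)
        except NotFoundSignal:
            first_len = float("nan")
        results.append(ZonationResult(
            root_id=f.root_id,
            condition=f.condition,
            meristem_cell_count_gmm=int(labels.sum()),
            meristem_run_from_qc=run,
            meristem_length_sum_um=float(f.lengths[labels].sum()),
            isodiametric_count=count_isodiametric(f),
            transition_count=count_transition(f),
            first_elongated_length=first_len,
            labels=labels,
        ))
    return results, fits
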