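# Methods

## Response statistics

**Responses are ratios of group means.** A seedling is measured once, in
one condition, so a per-seedling dark/darkW response does not exist; the
organ response is therefore mean(dark)/mean(darkW) over the seedlings of a
group, and the ratio adjustment factorises exactly as
response(hypocotyl)/response(root). The ratio-of-means estimator carries a
small positive bias of order CV²/n from the random denominator; at the
default n = 40 per group this is below 0.5% and ignored.

**Pairing.** Response quotients divide a mutant's response by its wild-type
ecotype's response computed from the *same plates* in the same replicate.
Multiplicative plate effects then cancel exactly in expectation, which is
why no mixed-effects model is fitted: the paired normalisation *is* the
plate correction. `summarize_replicate` refuses data in which a mutant sits
on a plate without a wild-type cohort.

**P-values.** The per-replicate P for each organ compares per-seedling
lengths between dark and darkW; the ratio P compares per-seedling
hypocotyl/root ratios, matching how the per-seedling ratio distributions
are visualised. Test selection is automated with a uniform rule:
Shapiro–Wilk on each group at α = 0.05 (constant groups are treated as
non-normal since Shapiro–Wilk is undefined for them); if either rejects,
two-sided Mann–Whitney-U; otherwise Levene's test at α = 0.05 chooses
Student's (equal variances) or Welch's t-test. Levene's was chosen for the
variance gate because it stays calibrated under the mild non-normality the
Shapiro gate lets through. Two identical constant samples return p = 1 with
a warning. The empirical type-I error of the full cascade is verified at
~0.05 in the acceptance suite. Benjamini–Hochberg adjustment (statsmodels'
step-up) is applied only across a family the caller declares — e.g. the
pairwise mitotic-index comparisons — never silently across everything.

**Aggregation.** Per genotype: arithmetic mean of RQs, median of P-values
(even counts: mean of the two central values), over biological replicates;
fewer than three replicates is flagged "insufficient". Mean organ lengths
(not medians) enter all responses.

**Classification thresholds.** RQ: attenuated < 0.8 ≤ normal ≤ 1.2 <
exaggerated (boundaries normal-inclusive). P: insignificant ≥ 0.05 >
attenuated significance ≥ 1e-5 > significant. The confused quadrant uses
the 1e-5 boundary, not 0.05: genotypes with attenuated ratio RQ and median
P of a few millis still classify as confused, which is the membership the
screen's exemplar mutants require. "Inverse direction" is operationalised
as: mutant and wild-type responses both individually significant
(p < 0.05) and on opposite sides of 1.

**Geometry.** Hypocotyl volume is V = πWL exactly as published, despite the
dimensional oddity of a cylinder formula without a squared radius; the
conventional π(W/2)²L is available behind `cylindrical_radius=True`
(default off) so comparisons against the published numbers stay faithful.
The fold-change "contribution" of cell geometry to organ geometry is
100·FC_cell/FC_organ; a (FC−1)-based share was rejected because observed
contributions can exceed 100%, which only the straight ratio produces.

## Root meristem zonation

**Mixture model.** Cell lengths pooled per condition are fitted with a
two-component Gaussian mixture by EM. Initialisation is deterministic —
split the sorted sample at the median, initialise each component from one
half — which is robust for the well-separated short/long populations of
meristem vs elongation zone; seeded random restarts are available via
`n_restarts`. Convergence: relative log-likelihood change < 1e-8, at most
500 iterations; variances floored at 1e-6 µm², hitting the floor flags the
fit degenerate. The log-likelihood trace is asserted non-decreasing on
every fit. Cells with posterior strictly greater than 0.8 for the
smaller-mean component are meristematic. Meristem size is reported two
ways — total meristematic-cell count and the contiguous run from the QC —
because published figures are compatible with either reading.

**Scan rules.** Isodiametric count: contiguous run from the QC of cells
with length ≤ width, stopping at the first longer-than-wide cell (a
whole-file count would conflate isodiametric cells re-appearing distally).
Transition count: from that first longer-than-wide cell, extend while each
next cell's length stays strictly under 1.5× its predecessor's; the scan
stops at the first ratio ≥ 1.5 (contiguous-run reading of the 150% rule).
Mature cell length: mean of the k = 10 most elongated cells pooled per
condition (the legend reads per condition, not per root). First elongated
cell: the lowest-index cell not labelled meristematic.

**Positional curves.** Pooled (cell index, value) points are smoothed by
tricube-weighted local polynomial regression — span 0.75, degree 2, the
conventional loess defaults — evaluated on the integer index grid. The
window is the ceil(span·n) nearest points, widened automatically (with a
warning) if it cannot support the polynomial degree. Confidence bands are
percentile bootstrap over whole roots (the experimental resampling unit),
200 resamples, seeded. The maximum fitted slope and its index are reported
as the elongation-onset diagnostics. This smoother is implemented here
because the available lowess routine supports neither degree 2 nor
evaluation on an arbitrary grid with root-level bootstrap.

## Synthetic data: what it emulates, and what not

Per-seedling organ lengths are Gaussian per (genotype, condition), means
only published as bar-graph shapes, so defaults are plausible magnitudes
chosen once: dark hypocotyl 10 ± 1.5 mm over root 3.0 ± 0.8 mm; darkW the
trade-off at 5 ± 1.0 mm over 9 ± 3.0 mm, the root variance inflated ~3×,
which is the condition's hallmark. Plate effects are multiplicative
log-normal (sd 0.1) per organ and plate; the magnitude is a choice, since
only the existence of lot/plate variation is documented. Non-positive
draws are resampled rather than truncated-renormalised (negligible mass at
these CVs). Genotype classes act through response multipliers on the
dark→darkW response, so the configured multiplier *is* the expected RQ —
the parameter-recovery acceptance checks exactly that. The confused class
ignores water withdrawal (darkW means equal dark means) with inflated
noise: its attenuated RQ_ratio and weak P are consequences of the stated
phenotype, not tuned outputs. Cell files place `meristem_cell_count` short
cells (8–8.5 ± 1.5 µm, width 16 ± 2 µm, hence isodiametric on average)
before a geometric elongation zone (rate 1.25–1.6 per cell) capped at the
mature length (110–160 µm); darkW gets the smaller meristem, earlier onset
and steeper rate. Mitotic counts are Poisson with means 12/1/8
(light/dark/darkW), encoding the eight-fold dark→darkW increase.

A green test therefore establishes that the pipeline recovers what the
generator states — calibration, parameter recovery, orderings — not that
real seedlings behave this way: the generator has no germination-timing
variation, no within-plate spatial gradients, no measurement error model,
no dwarfism (mutant dark-condition means equal wild type), and cell files
have condition-independent widths.

## Numerical choices and degenerate inputs

- Ratio-of-means responses raise on zero means; RQ requires a positive
  wild-type response.
- Volcano y uses −log₁₀(median P) with P = 0 clipped to 1e-300 plus a
  warning.
- Mann–Whitney in the cascade uses scipy's default method: exact for tiny
  untied samples, normal approximation otherwise — completely separated
  n = 40 groups therefore saturate at p ≈ 1.4e-14.
- Fold-changes with a zero-mean denominator yield NaN with a warning.
- EM on a (near-)constant sample is rejected below 2 distinct values and
  degenerate-flagged when a variance floors.

## Known limitations

- The decision-mutant criteria are the three printed screen criteria;
  distinguishing perception vs execution vs decision mechanistically is out
  of scope.
- Bootstrap bands assume exchangeable roots within a condition; files of
  very unequal length weight long files more at distal indices.
- The spreadsheet reader is mapping-driven by design: external supplements
  have no documented layout, so the caller must name sheet and columns.
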