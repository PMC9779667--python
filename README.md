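# seedscreen

Phenotyping pipeline for hypocotyl/root growth trade-offs in germinating
*Arabidopsis* seedlings.

A seedling germinating in darkness elongates its hypocotyl in search of
light at the expense of root growth; water withdrawal (imposed with PEG,
measured as water potential in MPa) pushes the trade-off the other way,
promoting root growth. Screening mutants under the combined condition —
darkness plus water stress ("darkW") — exposes genotypes that perceive both
cues yet fail to *decide* between the competing growth programmes. This
package implements the statistics of such a screen, the classification of
its hits, and the root-tip cell-level analysis that explains the root
response, together with a synthetic-data generator so that every stage is
testable without any measurements.

## The statistics

For each organ, the response to water stress in the dark is a ratio of
group means,

```
response_organ = mean length (dark) / mean length (darkW)
```

and the trade-off readout is the ratio adjustment

```
ratio_adjustment = (hypocotyl/root)_dark / (hypocotyl/root)_darkW .
```

Because PEG plates vary lot-to-lot, every mutant is normalised to its
wild-type ecotype grown on the same plates, giving response quotients

```
RQ = response_mutant / response_wildtype        (RQ = 1 ⇒ wild-type-like).
```

Significance of each response comes from a test-selection cascade
(Shapiro–Wilk normality gate → Levene's equal-variance gate → Student's or
Welch's t-test, falling back to Mann–Whitney-U), with Benjamini–Hochberg
correction across declared comparison families. Genotypes are classified
by mean RQ (attenuated < 0.8 ≤ normal ≤ 1.2 < exaggerated) and median P
(insignificant ≥ 0.05 > attenuated significance ≥ 1e-5 > significant), and
plotted as a volcano (mean RQ vs −log₁₀ median P). A **confused** genotype
combines an attenuated ratio RQ with a weak P — the lower-left volcano
quadrant. A **decision mutant** additionally meets all three screen
criteria: ratio failure (attenuated RQ or an inverse organ response), weak
significance, and one organ exceeding wild-type length under darkW.

For the root tip, cell lengths along epidermal files from the quiescent
centre are modelled as a two-Gaussian mixture fitted by EM; cells with
posterior > 0.8 of the short component are meristematic. Rule-based counts
(isodiametric cells: length ≤ width; transition cells: each under 150% of
its predecessor) and loess-style positional curves with bootstrap
confidence bands complete the zonation picture. Hypocotyl geometry uses
V = πWL (as published) and 2D anisotropy = length/width.

## Worked example

```
python analysis/01_simulate_screen.py
python analysis/02_organ_responses.py
python analysis/03_classify_mutants.py
python analysis/04_meristem_zonation.py
```

The simulated screen contains one genotype per response class. Step 03
prints, for seed 2024:

```
    genotype_id  mean_rq_ratio  median_p_ratio    rq_label       p_label  confused  decision_mutant
          Col-0          1.000           0.000      normal   significant     False            False
     mut-normal          1.049           0.000      normal   significant     False            False
 mut-attenuated          0.625           0.000  attenuated   significant     False            False
mut-exaggerated          1.458           0.000 exaggerated   significant     False            False
    mut-inverse          0.154           0.373  attenuated insignificant      True             True
   mut-confused          0.194           0.587  attenuated insignificant      True             True
 mut-perception          1.044           0.000      normal   significant     False            False
```

The wild type self-normalises to RQ exactly 1 with strong significance; the
configured confused genotype (no adjustment to water withdrawal, inflated
noise) lands in the lower-left quadrant; the inverse-root genotype is the
full decision mutant, qualifying on all three criteria. Step 04 shows the
combined-stress signature at the root tip: a smaller meristem (15.3 vs 26.8
cells by the mixture call), an earlier and steeper elongation onset, a
longer first elongated cell, and an ~8-fold higher mitotic index under
darkW than in the dark.

The same stages are available as a CLI (`seedscreen simulate | organ-stats |
classify | meristem | report`) and as one orchestrated run
(`seedscreen report --config cfg.yaml`) that writes a result bundle with a
reproducibility manifest.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the complete pipeline from scratch with the given seed — simulating
the screen, classifying every genotype, and running the zonation and
mitotic analyses — and writes the results JSON (this artifact defines no
numeric targets, so the object is empty; the bundle lands next to it).

See `docs/methods.md` for model assumptions, parameter defaults and known
limitations.
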