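# Methods

## Statistical model and procedure

The unit of analysis is the probeset (Affymetrix-style; probesets map
ambiguously to genes, so no gene-level collapsing is attempted). The
quantitative input is a probeset × sample matrix of log2-scale
normalized intensities (RMA-type values); normalization itself is out
of scope and assumed done upstream. Samples carry (animal, tissue, sex)
annotation; tissues are analysed independently.

Per tissue, each probeset receives: per-sex means of the log2 values
(means of log-scale values, never of linear intensities), their
difference Δ = x̄_M − x̄_F, a classical pooled-variance two-sample
Student *t* (df = n_M + n_F − 2, two-tailed), and a
Benjamini–Hochberg step-up q-value computed within that tissue. The SDE
call requires, with strict inequalities: expression above the
background floor in at least one sex, |Δ| > the fold threshold, and
q < the FDR level. Bias is the sign of Δ (male-biased if positive).

Cross-tissue aggregation classifies every probeset by its set of SDE
tissues: `always_male` / `always_female` when all biases agree,
`opposite` when both directions occur, `none` otherwise; "expressed in
a tissue" always reuses criterion 1, so one expression definition
serves breadth statistics and SDE calling alike. Probesets SDE in a
strict majority of tissues ("ubiquitous SDE"; in practice the
female-exclusive Xist-like and male-exclusive Eif2s3y-like probesets)
are detected by a majority-fraction rule rather than a hard-coded list,
and are excluded by default from per-tissue incidence totals, sharing
analysis and the clustering matrix, where they would otherwise
dominate.

### Sharing enrichment

The sharing universe is the set of probesets SDE in ≥ 2 tissues after
the ubiquitous exclusion. With n_X the per-tissue counts inside that
universe and T = Σ C(k, 2) the pair-weighted total, the chance
expectation for a tissue pair is expected = frac_A · frac_B · T with
frac_X = n_X / T (equivalently n_A·n_B/T). This denominator convention
is the one under which the published survey's printed enrichment
factors are internally consistent; it is exposed as the single
implemented convention and exercised by the worked-example tests. Note
frac values are weights, not probabilities (they do not sum to 1), and
the formula is a heuristic chance model rather than the mean of a
permutation null: resampling each probeset's tissue set with
frac-proportional weights does **not** give mean enrichment 1 under
this formula. The Monte-Carlo oracle therefore defaults to the
generative reading of the formula itself — each of the T pair slots
hits pair (A, B) with probability frac_A·frac_B, i.e. per-pair
Binomial(T, frac_A·frac_B) counts — which is mean-one by construction
and supplies per-pair null quantiles for judging planted or observed
excesses. The set-resampling null remains available
(`method="resample_sets"`) for sensitivity analysis.

### Validation suite

Three artefact checks for a tissue's SDE signal: (1) Pearson
correlations of every unordered sample pair over the tissue's SDE
probesets, *after centering each probeset across the tissue's samples*
— raw log2 profiles of any two arrays correlate near 1 through shared
expression-level structure, so centering is what makes the same-sex vs
cross-sex contrast informative. Which probesets and what preprocessing
underlie the published same-/cross-sex correlation figures is not
documented, so the subset is an explicit parameter and those published
values are not asserted. (2) Ward clustering of samples with a perfect
two-group sex-segregation flag. (3) Concordance of Δ values with other
tissues over the reference tissue's SDE set (Pearson r and
sign-agreement); a genuine signal shows attenuated-but-correlated
Δ in adjacent tissue and no correlation in an unrelated one.

### Clustering and MA plots

The ratio matrix holds Δ for probesets SDE in 1–4 tissues (ubiquitous
excluded) in *all* tissues, SDE or not — the off-call cells are what
reveal cross-tissue patterns — with one global symmetric colour bound.
Two-way clustering is Ward on Euclidean distances in the Ward.D2
convention (merge heights are roots of within-cluster
variance increases); the named criterion is covered by an independent
Lance–Williams oracle in the test suite. MA coordinates are
M = Δ, A = (x̄_M + x̄_F)/2; the transform is invertible.

## Tunable parameters

| parameter | default | units | note |
|---|---|---|---|
| `expr_threshold` | 6.65 | log2 intensity | background floor; a plain config value with no derivation, kept configurable |
| `min_abs_log2_diff` | 1.0 | log2 | two-fold rule |
| `max_q` | 0.05 | probability | BH level, per tissue |
| `bh_scope` | `all` | — | BH universe: all probesets with a computable p, or only expressed ones. The original analysis does not state its choice; both are supported, neither asserted |
| `welch` | off | — | unequal-variance t as a sensitivity option; the default follows the classical Student test |
| `ubiquitous_majority` | 0.5 | fraction | strict-majority rule for ubiquitous SDE |

Degenerate inputs: zero pooled variance with equal means gives t = 0,
p = 1; with unequal means it gives p = 0 plus a `degenerate_variance`
flag rather than an error, so noise-free synthetic data flows through
the pipeline. NaN p-values propagate to NaN q and shrink the BH test
count. Ties in clustering resolve deterministically by index.

## The synthetic-data generator

`SimulationConfig` defaults reproduce the survey-scale conditions:
26 named tissues × 2 sexes × 5 replicates, 31,042 probesets with
~61% expressed in ≥1 tissue. Values are
baseline + (effect/2)·(±1 by sex) + N(0, noise_sd), so the MA "A"
coordinate is effect-invariant. Specifics:

* **Breadth design.** 25% of expressed probesets are expressed in all
  tissues, 15% in exactly one, the rest in a uniform random 2..25
  subset.
* **Baselines.** Expressed cells sit at 7.2 + Exp(1.5) log2 units with
  N(0, 0.3) tissue wobble; background cells at N(4.5, 0.5), far enough
  below the 6.65 floor that sample means essentially never cross it.
* **Planted effects.** Per-tissue SDE fractions follow the survey's
  skewed incidence profile (duodenum ≈ 6.2% of expressed-anywhere
  probesets, zero in half the tissues), drawn from each tissue's
  expressed pool with weight breadth^−1.5 — sex-biased genes are
  less often ubiquitously expressed than unbiased genes, and uniform
  selection would invert that contrast. Magnitudes are
  1.25 + Exp(0.75) log2 units (all beyond two-fold), male-signed with
  probability 0.6.
* **Shared blocks.** Extra probesets planted SDE in both members of a
  pair (defaults: duodenum–kidney +30, adrenal–pituitary +14, the two
  above-chance pairs of the survey), with the second tissue's sign
  flipped with probability 0.48 to populate the opposite-bias class.
* **Sex-exclusive genes.** Five Xist-like female-only and one
  Eif2s3y-like male-only probesets (one sex at a 10.0 plateau, the
  other at background, every tissue) plus one compensating homolog at a
  uniform 1.7-fold female bias — below the two-fold criterion, as for
  Eif2s3x.
* **Attenuation.** Duodenum effects echo into jejunum (×0.3) and ileum
  (×0.15): the same skew, mostly below the calling criteria, matching
  the observed weak cross-calling between gut sections while preserving
  fold-difference concordance. Tests of the concordance gradient set
  their own steeper {0.5, 0.25} ladder explicitly.
* **No animal random effect** is simulated (the downstream test is a
  plain two-sample t); animal ids are annotated for completeness.
  Noise is Gaussian on the log2 scale.

What the generator does **not** emulate: probe-level/affinity
structure, intensity-dependent variance, batch effects, correlated
gene modules beyond the planted blocks, and non-Gaussian tails. Tests
passing on this generator therefore demonstrate correctness of the
statistics and bookkeeping under the assumed model, not robustness to
microarray artefacts the model omits.

Determinism: one `numpy` Generator seeded from the config (or an
override) drives all sampling; identical seeds give bit-identical
matrices.

## Worked-example inputs

`dimorph.reference_tables` carries the printed summary counts of the
published 26-tissue rat survey (chip totals, the bias-class ×
tissue-count distribution, duodenum incidence, two sharing records) as
inputs for arithmetic the tabulation/enrichment operations must
reproduce. Because the survey's supplementary incidence workbook is not
shipped, the module constructs a **synthetic** stand-in incidence
matrix consistent with those printed margins (exact k-distribution by
bias class; duodenum–kidney sharing of 101; duodenum per-sex totals)
and can write it as an XLSX workbook for exercising the
layout-configurable supplementary reader end to end. Cells not pinned
by the printed margins are placed deterministically and are not
asserted anywhere.

## Problem sizes

The test suite uses simulations of 600–4,000 probesets (one shared
2,500-probeset, 26-tissue dataset for cross-module tests); the
acceptance script runs the full 31,042 × 260 default once plus a
500-replicate Monte-Carlo null. Both complete in seconds.

## Known limitations

* The enrichment chance model is the survey's own heuristic; its
  `frac` weights are not probabilities and the statistic has no
  calibrated p-value — the Monte-Carlo null quantiles are the
  inferential tool.
* BH is applied per tissue with no cross-tissue multiplicity control,
  mirroring the original design.
* The sample-pair correlation check depends on the chosen probeset
  subset; with the SDE subset it is intentionally anti-conservative as
  a *descriptive* artefact check, not a hypothesis test.
* `per_tissue_sde_rate` is interpreted relative to probesets expressed
  anywhere (the survey's denominator for per-tissue incidence), not to
  the tissue's own expressed pool.
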