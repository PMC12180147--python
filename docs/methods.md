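# Methods

## The CSLV representation

For sample *s* and segment *g* (a fixed run of markers on one
autosome), the chromosome-scale length variation value is the
arithmetic mean of the sample's observed log R ratios over the
segment's markers:

CSLV(s, g) = mean{ LRR(s, j) : j ∈ g, LRR observed }.

LRR is treated as an opaque dimensionless log-ratio; the toolkit never
re-bases it (log2 vs log10 does not matter to anything downstream,
since every operation is affine in the features). A value of 0 is the
nominal two-copy state; positive values indicate net duplication,
negative values net deletion over the segment. Only autosomes 1–22
participate; sex chromosomes are excluded by construction at ingestion.

### Segmentation

`make_segments(manifest, k, mode)` partitions each autosome's
position-sorted markers (ties broken by marker id, so the order is
deterministic) into `k` segments:

* `equal_marker_count` (default, `k=4`): maximal-balanced runs —
  sizes differ by at most one, larger runs first. Chosen as the
  default because it equalizes the sampling variance of segment means
  across segments and can never produce an empty segment.
* `equal_bp_span`: the bp extent [min, max+1) is cut into `k` equal
  intervals and markers assigned by position; sparse regions can leave
  a segment empty (warned, and the corresponding feature is missing).

Both are provided because "a quarter of a chromosome" is ambiguous
between marker rank and physical span; neither claims to be the one
true quartering, and with dense arrays they nearly coincide.

### Missingness

Two explicit levels, because "complete data" can reasonably be
enforced at either granularity:

* marker level: a segment value is the mean over *observed* markers,
  reported only if the observed fraction ≥ `min_observed_fraction`
  (default 0.9); otherwise the entry is missing. Nothing is imputed.
* sample level: `filter_complete` drops any sample with a missing
  segment value (complete-case rule) before modelling.

## The synthetic cohort model

`simulate_cohort` draws marker-level data as

LRR(i, j) = Δ_group(i)[seg(j)] + s[seg(j)]·I(male_i) + δ_cnv(i, seg(j)) + ε_ij,
ε ~ N(0, σ²) i.i.d.,

so each sample's expected LRR is piecewise constant over segments (the
"truth segment mean" recorded as ground truth) with i.i.d. marker
noise on top. Components and defaults:

* **σ = 0.15** with 100 markers/chromosome and k=4: segment means
  scatter with sd 0.15/√25 = 0.03, the order of magnitude seen in
  population histograms of per-chromosome mean LRR. This is a
  qualitative match, not a calibration.
* **groups** are phenomenological dosage-shift classes (a label plus a
  per-segment shift vector Δ), not ancestry models: no allele
  frequencies, no linkage disequilibrium. They reproduce exactly the
  statistical structure CSLV classification relies on — mean shifts —
  and nothing else.
* **sex crosstalk**: males receive an additive shift on a subset of
  autosomal segments (default +0.02 on the first segment of
  chromosomes 1–8), emulating probe-design leakage of Y presence into
  autosomal intensities. The magnitude is a modelling choice, not a
  measured value.
* **CNV events**: per (sample, segment) with probability `cnv_rate`,
  copy number 1 or 3 equiprobably, shifting the whole segment by
  δ₁ = −0.45 or δ₃ = +0.30 — the conventional attenuated LRR levels
  for one-copy loss/gain on arrays. Configurable.
* **height** (cm): intercept 165 + 13·I(male) − 0.06·(age − midpoint
  of the age range) + γ·(truth segment means) + N(0, 6²). The negative
  age slope encodes the age-cohort effect (older cohorts are shorter);
  ages are uniform on [21, 80] by default so the adult filter (≥ 21)
  at the modelling stage is non-trivial only when the range is
  widened. γ (cm per LRR unit) carries the heritable dosage signal.
* **BAF** is written as a constant 0.5 placeholder in long exports —
  it is parsed and discarded on read, so no fidelity is attempted.

Randomness: each draw comes from
`SeedSequence(seed, spawn_key=(component, sample_index))` with
components phenotype / cnv / noise, so two cohorts with the same seed
are identical byte for byte, and enlarging `n_samples` appends samples
without perturbing existing ones.

### The analytic AUC oracle

For two groups differing only in Δ (no CNV, no crosstalk — the
function refuses otherwise), the CSLV features are Gaussian with equal
covariance and the optimal linear discriminant achieves

AUC = Φ(D/√2),  D² = Σ_g ((Δ₁[g] − Δ₂[g]) √m_g / σ)²,

with m_g the segment's marker count. This closed form is the
independent yardstick the evaluation harness is calibrated against.

## The evaluation harness

* **AUC** uses the Mann–Whitney convention: ties between a positive
  and a negative score count half. The reported value is the
  trapezoidal area of the ROC curve with thresholds at every distinct
  score; the test suite checks it against exhaustive pair counting.
* **Task construction**: classification keeps only the two requested
  labels; the height regression keeps adults (age ≥ 21), drops missing
  heights, and uses age plus the CSLV columns as the only predictors —
  sex and group label are deliberately withheld so any sex structure
  in the predictions must come through the features.
* **split_counts** uses the floor of n·fraction, with a tiny
  snap-to-integer guard so exact products (161,820 × 0.8 =
  129,456/32,364) are immune to binary floating point.
* **model_search** replaces a wall-clock AutoML budget with a
  deterministic trial budget (default 24) over a fixed zoo:
  regularized logistic/ridge ("GLM"), histogram gradient boosting
  ("GBM"), random forest ("DRF") and a small (32, 16) feed-forward
  network ("deep learning"), each with a small fixed hyperparameter
  grid, interleaved across families so truncation keeps every family.
  Every candidate is scored by its out-of-fold predictions on one
  shared k-fold partition (stratified for classification; AUC or
  RMSE). Two stacked ensembles — a regularized linear meta-learner
  over all candidates and over the best of each family — are scored by
  fold-wise refits of the meta-learner on the out-of-fold prediction
  matrix (the base predictions for a fold's training rows were made by
  models that saw some of those folds, a mild optimism shared by
  AutoML-style leaderboards and accepted here for speed). The winner
  is refit on the full training table (ensembles via
  scikit-learn stacking with the same fold plan).
* **repeated_holdout** redraws a split whose test half is
  single-class, logging each redraw, and gives up after 10 attempts.
  The sd is across repeats (ddof=1). Where both cross-validated and
  repeated-split numbers exist they are reported separately, never
  mixed.
* **grouped_mean_curve** ranks by prediction (stable sort, so input
  order breaks ties), cuts into maximal-balanced contiguous groups
  (larger first) and reports per-group mean predicted and actual.
* **permutation_importance** is the implemented variable-importance
  analog of per-feature contribution plots: the drop in held-out
  performance (AUC, or negated RMSE, so useful features are positive
  either way) when one column is shuffled, averaged over repeats with
  a per-report RNG. SHAP-style attributions are out of scope and the
  reports say so.

## Benchmark problem sizes

The preset cohorts used by the test suite and the reproduction script
were sized so each benchmark estimates its quantity with useful
precision while a full run stays within a few minutes on one CPU:

* oracle-calibration cohorts: n = 2000 (weak ≈ 0.760, strong ≈ 0.943,
  null = 0.5), five 80/20 repeats of a regularized logistic recipe —
  the Bayes-optimal family for these Gaussian problems, so the
  measured AUC should approach the closed form from below within
  Monte-Carlo error (±0.02).
* shift recovery: 10,000 samples, one 400-marker segment, σ = 0.2,
  injected shift +0.3; the CLT predicts 99.7% of estimates within
  3σ/√400 = ±0.03.
* height curve: n = 4000 (50 groups of 80), trial budget 4 with
  5-fold CV; crosstalk raised to +0.04 on 8 segments so the analytic
  sex AUC from features alone is ≈ 0.996, mirroring near-perfect sex
  recovery from autosomal dosage; heritable signal from CNV events
  (rate 0.02) weighted 20 cm/LRR on 20 segments. The two-level
  structure statistic compares the largest jump between consecutive
  group means (the sex gap) to the median of the remaining jumps.
* importance diffusion: n = 2000, 88 features with equal signal
  (standardized shift 0.5) on 20 segments; shares are computed over
  the positive part of the importance mass.

## What passing tests do and do not show

The simulator reproduces the *first-order* structure CSLV relies on:
segment-mean shifts, their noise scaling with marker count, and
sex-linked leakage. It does not model GC waves, batch effects,
population stratification of marker noise, linkage disequilibrium, or
real CNV length distributions (events always span whole segments).
Passing the calibration suites therefore shows the pipeline is correct
and unbiased under its stated model — not that any particular AUC is
attainable on real array data, where those unmodelled effects can cut
both ways.

## Known limitations

* CSLV deliberately discards within-segment information; it is a
  screening representation, not an interpretable fine-mapping tool.
* The leaderboard's ensemble scores share folds with their base
  models' out-of-fold predictions (see above); treat small
  ensemble-vs-single-model gaps as ties.
* Long-format export scales as samples × markers rows; use the wide
  format for large cohorts.
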