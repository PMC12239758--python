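# Methods

## k-mer signature extraction

A sample's signature is the relative-frequency vector over the full
4^k vocabulary of DNA words (A < C < G < T, lexicographic column order).
Counting uses a stride-1 sliding window over each read independently —
windows never span reads, so pooling paired-end mates into one read stream
preserves all frequencies. The engine consumes raw FASTQ (plain or gzip,
sniffed from the magic bytes) with no quality trimming, host depletion or
taxonomic classification: retaining unclassifiable reads is the point of
the representation.

Conventions, chosen where a raw-counting scheme is underdetermined:

- **Ambiguous symbols.** Windows containing any non-ACGT symbol are skipped
  and tallied in `n_skipped_windows`. Skipping keeps the feature universe
  at exactly 4^k; mapping N to a fifth symbol or to a random base would
  either inflate the vocabulary or inject noise.
- **Strand.** No reverse-complement canonicalization by default (the
  vocabulary is the full 4^k enumeration). `canonicalize_table` /
  `extract --canonical` folds complementary columns for strand-agnostic
  protocols.
- **Exactness.** Per-sample counts are accumulated as 64-bit integers and
  divided once at the end, so signatures are bitwise identical across read
  order, batch boundaries (default 128 lines per cycle, configurable) and
  worker counts; parallelism is across samples only.
- **Degenerate inputs.** Reads shorter than k contribute nothing; a sample
  with zero valid windows raises an error naming the sample rather than
  emitting a NaN row.
- **Coordinates.** Windows are 0-based half-open [i, i+k); `k` is capped at
  12 because a dense 4^k vector beyond that stops being a sensible
  in-memory representation.

## Preprocessing chain

Order: SMOTE → standardization → LASSO selection → PCA, fitted on the
training partition of each fold and applied unchanged to validation data.

- **SMOTE** (k = 5 minority neighbors, Euclidean): each synthetic point is
  x_i + u·(x_nn − x_i), u ~ U(0,1). A singleton minority class falls back
  to duplication with a warning. Oversampling is implemented in-package and
  is applied strictly to the training partition.
- **Standardization**: per-column mean/SD from the (augmented) training
  data; near-zero SDs (relative round-off of a constant column) are treated
  as zero variance and those columns scale to ~0 instead of exploding —
  plausible columns on sparse 7-mer tables.
- **LASSO**: L1-penalized logistic regression; the penalty is chosen by an
  internal stratified 5-fold CV maximizing ROC AUC over a 21-point
  logarithmic grid (C from 10^-2.5 to 10^2.5). A binary outcome calls for
  the logistic link; an L1 linear model on 0/1 labels is available behind
  `lasso.link: linear`. If the chosen penalty zeroes every coefficient the
  weakest penalty retaining ≥1 feature is used (warned); if none does, all
  columns are kept.
- **PCA**: target 16 dimensions, capped at min(16, rank, #selected,
  #samples). The basis is fitted on the standardized selected training
  columns (full SVD, deterministic).

**Scope.** The default `per-fold` scope guarantees validation rows never
touch any fitted statistic — SMOTE, scaler, LASSO and PCA all see training
rows only, which the test suite asserts by corrupting validation rows and
checking the fitted statistics are unchanged. A `global` scope (scaler,
LASSO and PCA fitted once on the full table before cross-validation, SMOTE
still fold-internal, necessarily applied in the already-transformed space)
is provided because published analyses often quote a single selected-feature
count per task, which only a global fit produces; it is optimistic and
labelled as such.

## Classifiers

- Logistic regression: scikit-learn, max 1,000 iterations, default L2
  regularization (C = 1, recorded in provenance).
- Linear SVM: scikit-learn SVC, linear kernel, C = 1, Platt-calibrated
  probability outputs.
- Gaussian naive Bayes: scikit-learn defaults (variance smoothing 1e-9).
- Feed-forward network: an in-package NumPy implementation of the fixed
  architecture dense(16, ReLU) → dropout(0.5, inverted) → dense(4, ReLU) →
  dense(1, sigmoid), Glorot-uniform init, Adam on binary cross-entropy,
  minibatches of 32, at most 50 epochs. Early stopping (patience 10,
  best-weights restore) monitors an internal stratified 10% split of the
  training fold — using the CV validation fold would leak. The Adam step
  size is 5e-3 rather than the common 1e-3: with ≤50 epochs on
  cohort-sized data there are only a few hundred updates, and at 1e-3 the
  loss does not reliably converge within the budget (the separable-blob
  sanity check settles around 0.86 training accuracy; at 5e-3 it reaches
  1.0 across seeds).

All stochastic components (fold shuffling, SMOTE draws, LASSO internal CV,
FFNN init/dropout/batching, bootstrap resampling) descend from the single
pipeline seed; per-fold and per-model seeds are derived deterministically,
so a run is exactly reproducible end to end.

Hard labels are score > 0.5 everywhere votes or confusion matrices are
needed. Youden-optimal thresholds are reported as a metric but never used
for voting.

## Ensemble

Per-model ROC AUCs are scaled into weights w_m = AUC_m / Σ AUC (all-zero
AUCs fall back to uniform; an alternative max(AUC − 0.5, 0) rule sits
behind `ensemble.weight_rule: excess`). The integrated prediction is the
weighted sum of hard votes; a sample is positive when the weighted vote
score exceeds 0.5, with an exact tie (measure-zero for four distinct
weights) resolved to positive. The continuous vote score is also the
ensemble's ranking score for ROC/PR curves — hard votes alone would give a
degenerate 5-point curve, and the vote score is its minimal continuous
extension. By default the weight AUCs are measured on an internal
stratified 20% hold-out of each training fold (models are then refit on
the full fold); `ensemble.auc_source: fold-validation` weights by the CV
fold's own validation AUC instead, which mirrors some published setups but
is optimistic, and is labelled accordingly. Soft voting (weighted mean of
calibrated probabilities) exists behind `ensemble.soft` and is off by
default.

## Evaluation

- ROC AUC is the rank-based Mann-Whitney statistic (ties counted half),
  which agrees with trapezoidal integration of the empirical ROC curve.
- PR AUC uses step-wise interpolation (average precision); linear
  interpolation of PR points overestimates the area.
- 0/0 rates (e.g. precision with no predicted positives) are reported as 0
  with an `undefined` flag instead of NaN.
- MCC uses the convention that any zero denominator factor gives 0.
- Youden index = max over thresholds of sensitivity + specificity − 1.
- Fold aggregation: per-fold metrics averaged with population SD;
  pooled-prediction metrics over the concatenated validation sets are
  reported alongside (published single numbers may be either). Confusion
  matrices are averaged elementwise. The mean ROC curve is the vertical
  average of per-fold curves on a 101-point FPR grid with an SD band.
- Bootstrap CIs: percentile intervals over resampled (score, label) pairs,
  1,000 reps by default; resamples that lose a class are discarded. A
  simulation in the test suite checks ~95% coverage on a known binormal
  model.

## Synthetic cohorts

`generate_cohort` writes gzipped FASTQ plus a manifest; reads come from an
order-(k_signal − 1) Markov chain. Both classes share a base transition
matrix (a mild AT/GC skew alternating by context parity); class c receives
±(effect_size/2)·Δ, where Δ is a fixed zero-sum direction spreading the
perturbation over many k-mers, so 3-, 5- and 7-mer tables all carry graded
signal — injecting composition-level signal rather than literal motif
spikes mirrors how short k-mers can already separate cohorts. Per-sample
variability is a Dirichlet resample of each transition row with
concentration α (default 1,000, i.e. per-row jitter SDs of roughly 0.01 —
visible but smaller than the default class effect). effect_size = 0 makes
the class laws identical, giving a proper null. Quality strings are
constant dummies because the extraction path ignores quality.

Defaults (50 samples per class, 2,000 reads × 150 bp, k_signal = 3,
effect_size = 0.2, α = 1,000) are the conditions under which the
signal-recovery property is stated: cross-validated AUC ≥ 0.9 for the FFNN
and the integrated model, and chance-level AUC ∈ [0.35, 0.65] for every
model at zero effect. What the generator does **not** emulate: sequencing
error profiles, quality variation, host contamination, amplicon primer
structure, variable read lengths, or realistic genome-scale linkage between
k-mers. Passing these tests therefore demonstrates that the machinery
recovers compositional class differences without leakage — not that any
particular real cohort is separable.

Problem sizes used by the test suite and the acceptance script (null
calibration at 300 reads/sample, generator self-checks at 40–200
reads/sample) are the package's own choices: read depth beyond a few
hundred reads changes per-sample multinomial noise negligibly relative to
the Dirichlet jitter, so these checks are insensitive to depth.

## Known limitations

- Binary tasks only; multi-class labels are collapsed through the task's
  label mapping (e.g. {CD, UC} → IBD).
- Dense counting caps k at 12; larger k needs sketching or disk-backed
  counters, deliberately out of scope.
- The global preprocessing scope and fold-validation weight source exist
  for comparability with published setups and are both optimistic; the
  defaults (per-fold, inner-validation) are the statistically sound
  choices.
- SVM probability calibration (Platt) adds its own internal CV and is the
  slowest base model on large folds.
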