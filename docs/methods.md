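# Methods

This note documents the models and procedures implemented in `ersknn`,
the defaults chosen where the literature leaves the design open, and what
the synthetic test bed does and does not demonstrate.

## Signal model and preprocessing

Motor-imagery classes are assumed to differ in the spatial distribution of
8-30 Hz band power (event-related desynchronisation/synchronisation of the
mu and beta rhythms). Epochs are band-passed with a third-order Butterworth
filter, 8-30 Hz by default (`FilterSpec(low_hz, high_hz, order, mode)`).

* `mode="zero_phase"` (default) applies the filter forward-backward
  (effective order 6, zero group delay). Zero-phase filtering is standard
  for epoch-based CSP pipelines because phase distortion would bias the
  covariance estimates; `mode="forward"` is available where strict
  third-order causal behaviour is wanted.
* Epoch ends are reflect-padded (about one filter length) before
  filtering; epochs are short and unpadded start-up transients would
  corrupt per-trial covariances.
* `downsample` requires an integer decimation factor and applies an
  8th-order Chebyshev type-I low-pass at 0.8x the target Nyquist
  (zero-phase) before dropping samples; a polyphase `allow_resample` mode
  handles non-integer ratios explicitly rather than silently.
* Window selection uses half-open `[start, end)` intervals with sample
  index `floor(t * fs)`, so composed crops equal the intersected crop and
  no boundary sample is counted twice.

## Common Spatial Pattern

Per-trial covariances are trace-normalized (`A Aᵀ / trace(A Aᵀ)`) so that
only spatial structure, not global trial power, enters the class means.
The two-class filters solve the generalized eigenproblem
`C_a w = λ (C_a + C_b) w`, implemented as the canonical two-step
construction: eigendecompose the composite `C_r = U Λ Uᵀ`, whiten with
`P = Λ^(-1/2) Uᵀ`, eigendecompose `P C_a Pᵀ = B D Bᵀ`, filters
`W = Bᵀ P` sorted by descending D. In whitened space the two classes'
eigenvalues are complementary (sum to 1 per component), which the test
suite checks to 1e-8 against an independent generalized-eigenproblem
solve.

Numerical choices:

* Shrinkage `C ← (1-γ) C + γ (trace(C)/Ch) I` with γ = 1e-8 is always
  applied to the composite; if the raw composite is rank-deficient
  (condition worse than 1e9) γ is raised to 1e-4 with a warning. Many-
  channel covariances from short epochs are routinely near-singular.
* Filter rows have their first non-negligible coefficient made positive,
  so output is reproducible across eigensolver sign conventions.
* Multiclass uses one-vs-rest: the "rest" covariance is the mean
  normalized covariance over all non-target trials pooled, weighting
  classes by trial count. The k subproblems' features are concatenated
  into one vector per trial (an alternative would train k separate
  binary classifiers; concatenation keeps a single downstream model).
* Features are the raw sample variances (denominator Z-1) of the first
  and last `n_pairs` projected rows per subproblem (default `n_pairs=1`,
  i.e. 2 features per subproblem). A log-share variant
  (`log_variance=True`) is provided because it is field-standard, but is
  off by default.

## Random-forest feature selection

CART trees split on midpoints of consecutive sorted unique values,
maximising Gini (default) or entropy impurity decrease; ties break to the
lowest feature index, then the lowest threshold, so trees are fully
deterministic given their RNG stream. Forests grow `ntree=100` trees
(`max_splits=359`, candidate features per split `ceil(sqrt(p))`) on
bootstrap resamples of size n; out-of-bag indices are recorded per tree.
The importance forest is larger than a typical RF classifier baseline
(30 learners) because standardized importances need a stable σ estimate.

OOB permutation importance follows the error-difference scheme exactly:
per tree, the OOB error is compared before and after permuting one
feature's OOB values (a dedicated per-(tree, feature) RNG substream makes
the permutation independent of iteration order); features a tree never
splits on contribute d_tj = 0. The reported statistic is d̄_j / σ_j when
σ_j > 0, else d̄_j, with **higher = more important**; the raw per-tree
mean is available via `standardize=False`. (Printed versions of this
algorithm sometimes carry a minus sign on the standardized ratio, which
would make informative features negative; the sign here is chosen so the
ranking reads naturally.)

Two properties of the estimator worth knowing:

* d_tj values are strongly positively correlated across trees grown on
  one dataset, so `d_sd/sqrt(ntree)` understates the dataset-level
  uncertainty; null-importance checks in the test suite therefore average
  over independent dataset replicates.
* Features never used by any tree have importance exactly 0, not merely
  near 0.

`select_features` sweeps top-j prefixes in ranking order through a
user-supplied accuracy evaluator (the pipeline uses cheap stratified-CV
plain k-NN on the training fold) and returns the smallest j within
`tolerance` (default 0.5 accuracy points) of the best prefix — mirroring
the observation that a small selected set typically reaches near-maximal
accuracy.

## Random-subspace k-NN ensemble

Each of `n_learners=50` learners stores the full training set but
measures Euclidean (or Manhattan) distances only inside its own feature
subspace, drawn without replacement per learner from counter-based
substreams of the master seed (learner order cannot affect results). The
final class is the modal vote; vote fractions serve as one-vs-all ROC
scores.

* Subspace dimension defaults to `ceil(p/2)` with a floor of 2 (when
  p ≥ 2). The floor matters after aggressive feature selection: with two
  selected features, `ceil(p/2) = 1` would give single-feature learners,
  which cannot separate more than two classes and demonstrably break the
  effect-size monotonicity of the full pipeline.
* Tie rules are deterministic and distance-respecting: a k-NN vote tie
  goes to the class with the smaller summed neighbour distance, then the
  lowest class index; an ensemble vote tie to the class with the smaller
  aggregate neighbour distance over learners, then the lowest index.
* Optional per-fold z-scoring (`standardize=True`) is off by default:
  CSP variance features share a scale, and standardizing would distort
  the variance ordering the features encode.
* `tune_k` evaluates plain k-NN error over a log-spaced grid (default:
  unique rounded powers from 1 to n/2) by stratified CV, ties to the
  smallest k. The default fixed k is 10.

## Evaluation protocol

`stratified_folds` deals each class's shuffled trials round-robin with a
rotating offset, so every fold's class counts differ from proportionality
by at most one trial. `run_cv_pipeline` fits *every* supervised stage —
CSP, the selection forest, the prefix sweep, k tuning, the ensemble —
inside the training fold only. The test suite verifies the absence of
leakage by corrupting one fold's test labels and checking that a SHA-256
checksum over all fitted parameters of that fold is bit-identical.

Metrics: accuracy, sensitivity, specificity, FPR and error rate on the
percent scale; precision, recall, F1, Cohen's kappa (from the pooled
confusion-matrix marginals), generalized multiclass MCC and trapezoid
AUC on the unit scale. Binary reports quote the positive-class (class 0)
values; multiclass reports macro averages by default with micro values
alongside (micro recall equals overall accuracy by identity — the reason
accuracy and sensitivity rows can coincide in published multiclass
tables). Zero-denominator metrics are reported as NaN and named in
`flags`, never silently zeroed. Aggregation over folds/subjects uses the
arithmetic mean and sample SD (n−1); display rounding is half away from
zero at 2 decimals, implemented on the decimal representation so values
like 1.005 round up.

The AUC is computed by sweeping distinct score values in blocks, so it
equals the Mann-Whitney U statistic (1/2 tie convention) divided by
n₊ n₋ — important because ensemble vote fractions are heavily tied.

## Synthetic test bed

`generate` draws trials `x(t) = M s(t) + noise`: sources are white noise
filtered to 8-30 Hz (the same Butterworth the pipeline uses), normalized
to unit variance and scaled by per-class multipliers `class_power`;
`n_noise_channels` rows of M are zeroed. The per-class channel covariance
converges to `M diag(class_power[c]) Mᵀ + noise_sd² I` (verified to <10%
relative Frobenius error at 500 trials), which is precisely the model CSP
assumes, and the rows of `pinv(M)` are the ideal unmixing directions the
fitted filters are checked against.

Defaults are a desk-scale echo of public MI benchmarks: 8 channels (2
pure noise), 50 trials per class, 250 Hz, 2 s epochs, and a 4:1 planted
power ratio per class. `generate_feature_table` bypasses the signal
stages entirely: informative columns get a between-class mean shift of
`effect` standard deviations among label-independent N(0,1) noise
columns.

What passing tests on this bed do **not** show: robustness to real EEG
artifacts (ocular/muscle), session-to-session non-stationarity, volume-
conduction correlation structure, or subject variability. The generator
plants exactly the covariance structure the pipeline assumes, so results
on it are a correctness check of the machinery, not a performance claim
about real recordings.

## Problem sizes

The shipped tests and the acceptance script use 100-160 trials, 8-10
channels, 250 Hz, 10-fold CV, 60-200 trees and 20-100 selector
repetitions — sizes chosen so the full suite verifies every stage's
statistical behaviour in about a minute while leaving the estimators
comfortably in their stable regime.

## Known limitations

* The archive container stores float64 little-endian only; no chunking
  or compression (epoched MI datasets are small).
* `downsample` truncation follows `scipy.signal.decimate`'s length
  convention (`ceil(n/q)`), which differs by one sample from
  `floor(n·target/fs)` when q does not divide n.
* Trees are grown depth-first in Python; the forest is fast at BCI
  feature counts (≤ a few hundred features) but is not meant for
  thousands of features.
* One-vs-rest CSP with very unbalanced class sizes inherits the pooled
  "rest" weighting; no class re-weighting option is provided.
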