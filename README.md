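# ersknn

Classification of motor-imagery (MI) brain signals for brain-computer
interfaces: band-pass filtering, Common Spatial Pattern (CSP) feature
extraction, random-forest permutation-importance feature selection, and an
**e**nsemble of **r**andom-**s**ubspace **k-NN** classifiers, evaluated
under stratified 10-fold cross-validation.

The package is aimed at BCI researchers who work with epoched multichannel
EEG/ECoG trials (a `trials x channels x samples` tensor with per-trial
class labels) and want a compact, fully reproducible pipeline whose every
stage is testable against synthetic data with known ground truth.

## The method

Imagined movement modulates the 8-30 Hz sensorimotor rhythms (event-related
desynchronisation/synchronisation), so class information lives in the
*spatial distribution of band power*. The pipeline:

1. **Band-pass** each epoch, 8-30 Hz, third-order Butterworth
   (zero-phase by default).
2. **CSP.** For class covariances C_a, C_b (per-trial normalized
   covariance C = A Aᵀ / trace(A Aᵀ), averaged within class), solve
   C_a w = λ (C_a + C_b) w via whitening of the composite covariance.
   Projected variances along the first and last filters (eigenvalues near
   1 and 0; the two classes' eigenvalues sum to 1 per component) are the
   features. Multiclass problems are decomposed one-vs-rest into k binary
   subproblems whose features are concatenated.
3. **Feature selection.** A bagged CART forest is grown on the features;
   each feature's out-of-bag (OOB) permutation importance is
   VI_j = d̄_j / σ_j where d_tj = ε_tj − ε_t is tree t's OOB error
   increase after permuting feature j (d_tj = 0 when the tree never splits
   on j). Sweeping top-j prefixes against cross-validated accuracy picks
   the smallest subset within tolerance of the best.
4. **Classification.** 50 k-NN learners, each restricted to a random
   feature subspace, vote by majority; vote fractions give one-vs-all ROC
   scores. k is fixed or tuned by cross-validation on a log-spaced grid.
5. **Evaluation.** Stratified 10-fold CV with every supervised stage
   fitted inside the training fold only; accuracy, sensitivity,
   specificity, FPR, error rate, Cohen's kappa, precision, recall, F1,
   MCC and AUC from the pooled confusion matrix, plus fold-level
   mean ± SD.

A synthetic generator (`ersknn.synthetic`) emits trials
`x(t) = M s(t) + noise` with band-limited Gaussian sources whose per-class
variances are planted, so CSP/selector/classifier recovery can be verified
against known mixing directions.

## Worked example

```python
import numpy as np
from ersknn import SyntheticSpec, generate, PipelineConfig, run_cv_pipeline

tset, truth = generate(SyntheticSpec(n_classes=4, n_channels=10,
                                     n_trials_per_class=40, seed=7))
result = run_cv_pipeline(tset, PipelineConfig(seed=7))
m = result.pooled
print(f"pooled accuracy : {m.accuracy:.2f}%")
print(f"fold mean +/- SD: {result.aggregate.display()}")
print(f"kappa / MCC     : {m.kappa:.2f} / {m.mcc:.2f}")
print(f"macro AUC       : {m.auc:.2f}")
print(f"features kept   : {[int(s.size) for s in result.selected_features]}")
print("confusion matrix:"); print(m.cm)
```

prints

```
pooled accuracy : 95.62%
fold mean +/- SD: 95.63 ± 4.22
kappa / MCC     : 0.94 / 0.94
macro AUC       : 1.00
features kept   : [3, 3, 3, 3, 3, 3, 3, 3, 3, 3]
confusion matrix:
[[40  0  0  0]
 [ 1 38  0  1]
 [ 0  0 40  0]
 [ 2  2  1 35]]
```

160 four-class trials (10 channels, 4:1 planted band-power ratio per
class) are classified at 95.6% pooled accuracy — far above the 25% chance
level — with kappa/MCC ≈ 0.94, and the selector keeps only 3 of the 8
one-vs-rest CSP features in every fold. The same run with shuffled labels
drops to chance, confirming the pipeline fits no spurious structure.

The same workflow is available from the shell:

```sh
ersknn simulate --out trials.ersk --seed 7
ersknn evaluate --archive trials.ersk --out results/ --seed 7
ersknn report --result results/metrics.json
```

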