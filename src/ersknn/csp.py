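"""Common Spatial Pattern (CSP) feature extraction.

CSP finds spatial filters w that maximise the variance of one class's
projected signal while minimising the other's.  For class covariances
C_a, C_b it solves the generalized eigenproblem

    C_a w = lambda (C_a + C_b) w,

implemented here as the canonical two-step construction: eigendecompose the
composite C_r = C_a + C_b = U L U^T, whiten with P = L^{-1/2} U^T, then
eigendecompose P C_a P^T = B D B^T and take W = B^T P.  In whitened space
the class eigenvalues are complementary: diag(W C_a W^T) + diag(W C_b W^T)
= 1 component-wise, so the first row of W (eigenvalue near 1) captures the
direction where class a has maximal relative band power and the last row
(eigenvalue near 0) where class b does.  The per-trial variance of the
projected signal along the first and last n_pairs filters is the feature.

Multiclass problems are decomposed one-vs-rest: each of the k classes is
contrasted against the mean normalized covariance of all remaining trials
pooled, yielding k binary subproblems whose features are concatenated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


class DegenerateTrialError(ValueError):
    """Raised when a trial carries no signal power (zero trace)."""


def normalized_covariance(trial: np.ndarray) -> np.ndarray:
    """Spatial covariance of one trial, normalized to unit trace.

    ``trial`` is a channels x samples matrix A; the result is
    A A^T / trace(A A^T): symmetric, positive semi-definite, trace 1.
    Trace normalization removes per-trial global power differences so that
    only the *spatial distribution* of band power enters the average.
    """
    trial = np.asarray(trial, dtype=np.float64)
    if trial.ndim != 2:
        raise ValueError(f"trial must be 2-D channels x samples; got {trial.shape}")
    cov = trial @ trial.T
    tr = np.trace(cov)
    if tr <= 0 or not np.isfinite(tr):
        raise DegenerateTrialError(f"trial has degenerate power (trace={tr})")
    return cov / tr


def class_mean_covariance(tset, class_id: int) -> np.ndarray:
    """Mean of per-trial normalized covariances over one class's trials."""
    mask = tset.labels == class_id
    n = int(mask.sum())
    if n < 2:
        raise ValueError(
            f"class {class_id} has {n} trial(s); need >= 2 for a mean covariance"
        )
    return _mean_cov(tset.data[mask])


def _mean_cov(trials: np.ndarray) -> np.ndarray:
    acc = np.zeros((trials.shape[1], trials.shape[1]))
    for trial in trials:
        acc += normalized_covariance(trial)
    return acc / trials.shape[0]


@dataclass
class SpatialFilterBank:
    """CSP projection matrices, one entry per binary subproblem.

    ``filters[i]`` has shape (n_channels, n_channels): rows are spatial
    filters sorted by descending whitened-space eigenvalue ``eigenvalues[i]``
    (each in [0, 1]; the two classes' eigenvalues sum to 1 per component).
    ``subproblems[i]`` identifies the contrast, e.g. ``(0, "rest")`` or
    ``(0, 1)``.
    """

    filters: list[np.ndarray]
    eigenvalues: list[np.ndarray]
    subproblems: list[tuple]
    n_pairs: int = 1
    class_names: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.filters[0].shape[1]

    @property
    def n_features(self) -> int:
        return len(self.subproblems) * 2 * self.n_pairs


@dataclass
class FeatureMatrix:
    """Trials x features matrix with provenance names and aligned labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("labels not aligned with feature rows")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names not aligned with columns")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            labels=self.labels.copy(),
        )


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make the first non-negligible coefficient of each filter row positive."""
    W = W.copy()
    for i, row in enumerate(W):
        thresh = 1e-12 * max(np.abs(row).max(), 1e-300)
        nz = np.flatnonzero(np.abs(row) > thresh)
        if nz.size and row[nz[0]] < 0:
            W[i] = -row
    return W


def fit_csp_pair(
    cov_a: np.ndarray,
    cov_b: np.ndarray,
    shrinkage: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the CSP filters for one binary contrast.

    Returns ``(W, d)`` where W (rows = filters) simultaneously diagonalizes
    both covariances — ``W cov_a W^T = diag(d)`` with d descending and
    ``W cov_b W^T = diag(1 - d)``.

    Shrinkage ``C <- (1-g) C + g (trace(C)/Ch) I`` is applied to the
    composite before whitening; if the composite is still effectively
    rank-deficient the shrinkage is raised to 1e-4 with a warning, and an
    error is raised only if that too fails.  Short epochs over many channels
    routinely produce near-singular covariance estimates.
    """
    cov_a = np.asarray(cov_a, dtype=np.float64)
    cov_b = np.asarray(cov_b, dtype=np.float64)
    if cov_a.shape != cov_b.shape or cov_a.shape[0] != cov_a.shape[1]:
        raise ValueError(f"covariance shapes mismatch: {cov_a.shape} vs {cov_b.shape}")
    ch = cov_a.shape[0]
    comp_raw = cov_a + cov_b
    lam_raw = linalg.eigvalsh(comp_raw)
    if lam_raw[-1] <= 0:
        raise np.linalg.LinAlgError("composite covariance has no positive eigenvalue")
    gamma = shrinkage
    if lam_raw[0] <= lam_raw[-1] * 1e-9:
        gamma = max(shrinkage, 1e-4)
        warnings.warn(
            f"composite covariance is rank-deficient; raising shrinkage to {gamma:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    comp = (1.0 - gamma) * comp_raw + gamma * (np.trace(comp_raw) / ch) * np.eye(ch)
    lam, U = linalg.eigh(comp)
    if lam[0] <= 0:
        raise np.linalg.LinAlgError(
            f"composite covariance singular even after shrinkage {gamma:g}"
        )
    P = (U / np.sqrt(lam)).T  # P = L^{-1/2} U^T
    S_a = P @ cov_a @ P.T
    S_a = 0.5 * (S_a + S_a.T)
    d, B = linalg.eigh(S_a)
    order = np.argsort(d)[::-1]
    d = np.clip(d[order], 0.0, 1.0)
    W = _fix_signs(B[:, order].T @ P)
    return W, d


def fit_csp_multiclass(tset, n_pairs: int = 1, shrinkage: float = 1e-8) -> SpatialFilterBank:
    """Fit a CSP filter bank: one contrast for 2 classes, one-vs-rest for k > 2.

    The "rest" covariance is the mean normalized covariance over all
    non-target trials pooled, so classes are implicitly weighted by their
    trial counts.
    """
    classes = tset.classes_present()
    if classes.size < 2:
        raise ValueError(f"need >= 2 classes to fit CSP; got {classes.size}")
    counts = tset.class_counts()
    thin = [int(c) for c in classes if counts[c] < 2]
    if thin:
        raise ValueError(f"classes {thin} have < 2 trials; cannot estimate covariance")
    filters, eigenvalues, subproblems = [], [], []
    if classes.size == 2:
        a, b = int(classes[0]), int(classes[1])
        W, d = fit_csp_pair(
            class_mean_covariance(tset, a), class_mean_covariance(tset, b), shrinkage
        )
        filters.append(W)
        eigenvalues.append(d)
        subproblems.append((a, b))
    else:
        for c in classes:
            c = int(c)
            cov_c = class_mean_covariance(tset, c)
            cov_rest = _mean_cov(tset.data[tset.labels != c])
            W, d = fit_csp_pair(cov_c, cov_rest, shrinkage)
            filters.append(W)
            eigenvalues.append(d)
            subproblems.append((c, "rest"))
    return SpatialFilterBank(
        filters=filters,
        eigenvalues=eigenvalues,
        subproblems=subproblems,
        n_pairs=n_pairs,
        class_names=list(tset.class_names),
    )


def extract_features(tset, bank: SpatialFilterBank, log_variance: bool = False) -> FeatureMatrix:
    """Project trials through the bank and take per-row sample variances.

    For each trial A and each subproblem: X = W A; the features are the
    sample variances (denominator Z-1) of the first ``n_pairs`` and last
    ``n_pairs`` rows of X, concatenated across subproblems, giving
    ``subproblems * 2 * n_pairs`` features per trial.  ``log_variance``
    replaces each variance v with log(v / sum v) over the retained rows of
    the subproblem (field-standard normalisation, off by default).
    """
    if tset.n_channels != bank.n_channels:
        raise ValueError(
            f"channel mismatch: trials have {tset.n_channels}, bank expects {bank.n_channels}"
        )
    n_pairs = bank.n_pairs
    if not (1 <= 2 * n_pairs <= bank.n_channels):
        raise ValueError(f"n_pairs {n_pairs} out of range for {bank.n_channels} channels")
    cols = []
    names = []
    for W, sub in zip(bank.filters, bank.subproblems):
        keep = list(range(n_pairs)) + list(range(W.shape[0] - n_pairs, W.shape[0]))
        proj = np.einsum("fc,tcs->tfs", W[keep], tset.data)
        var = proj.var(axis=-1, ddof=1)
        if log_variance:
            var = np.log(var / var.sum(axis=1, keepdims=True))
        cols.append(var)
        tag = f"{sub[0]}v{sub[1]}"
        names.extend(f"csp[{tag}]:row{r}" for r in keep)
    return FeatureMatrix(
        values=np.hstack(cols), feature_names=names, labels=tset.labels.copy()
    )
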