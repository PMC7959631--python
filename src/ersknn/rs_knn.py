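"""Ensemble of random-subspace k-nearest-neighbour classifiers.

k-NN degrades in high-dimensional feature spaces; the random-subspace
remedy trains many k-NN learners, each restricted to a random subset of
the features, and combines their predictions by majority vote.  Each
learner stores the full training set but measures distances only inside
its own subspace, so learners make decorrelated errors while every one of
them remains a consistent classifier.

Deterministic tie-breaking throughout: a k-NN vote tie goes to the class
with the smaller summed neighbour distance, then to the lowest class
index; an ensemble-level vote tie goes to the class with the smaller
aggregate neighbour distance across learners, then to the lowest index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


def _check_metric(metric: str) -> str:
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}; got {metric!r}")
    return _METRICS[metric]


def _vote(dist_k: np.ndarray, labels_k: np.ndarray, n_classes: int):
    """Majority vote among k neighbours; returns (class, votes, class_dist_sums)."""
    votes = np.bincount(labels_k, minlength=n_classes).astype(np.int64)
    dsum = np.full(n_classes, np.inf)
    for c in np.unique(labels_k):
        dsum[c] = dist_k[labels_k == c].sum()
    top = votes.max()
    tied = np.flatnonzero(votes == top)
    winner = int(tied[np.lexsort((tied, dsum[tied]))[0]])
    return winner, votes, dsum


def knn_predict(
    train_X: np.ndarray,
    train_labels: np.ndarray,
    query: np.ndarray,
    k: int,
    metric: str = "euclidean",
) -> tuple[int, np.ndarray]:
    """Plain k-NN prediction for a single query vector.

    Returns ``(predicted class, per-class vote counts)``.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_labels = np.asarray(train_labels, dtype=np.int64)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if not (1 <= k <= train_X.shape[0]):
        raise ValueError(f"k={k} out of range for {train_X.shape[0]} training points")
    d = cdist(np.asarray(query, dtype=np.float64)[None, :], train_X,
              metric=_check_metric(metric))[0]
    nn = np.argsort(d, kind="stable")[:k]
    n_classes = int(train_labels.max()) + 1
    winner, votes, _ = _vote(d[nn], train_labels[nn], n_classes)
    return winner, votes


@dataclass
class RSKNNModel:
    """Fitted random-subspace k-NN ensemble (a lazy learner: stores the data)."""

    train_X: np.ndarray
    train_labels: np.ndarray
    subspaces: list[np.ndarray]
    n_learners: int
    k: int
    metric: str = "euclidean"
    seed: int = 0
    standardize: bool = False
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    n_classes: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_classes == 0:
            self.n_classes = int(self.train_labels.max()) + 1


def fit_rs_knn(
    X,
    labels=None,
    n_learners: int = 50,
    k: int = 10,
    subspace_dim: int | None = None,
    metric: str = "euclidean",
    seed: int = 0,
    standardize: bool = False,
) -> RSKNNModel:
    """Fit the ensemble: sample one feature subspace per learner, store data.

    ``X`` may be a FeatureMatrix (labels taken from it) or an array plus
    ``labels``.  ``subspace_dim`` defaults to ceil(p/2) with a floor of two
    dimensions (when p >= 2): single-feature k-NN learners are too weak to
    separate more than two classes after aggressive feature selection.
    Subspace draws
    are without replacement within a learner and independent across
    learners, via counter-based substreams of ``seed`` so learner order
    never matters.  Optional z-scoring (fit on the training data) is off by
    default: CSP variance features already share a scale.
    """
    values = X.values if hasattr(X, "values") else np.asarray(X, dtype=np.float64)
    if labels is None:
        labels = X.labels
    labels = np.asarray(labels, dtype=np.int64)
    n, p = values.shape
    if subspace_dim is None:
        subspace_dim = min(p, max(2, int(math.ceil(p / 2))))
    if not (1 <= subspace_dim <= p):
        raise ValueError(f"subspace_dim={subspace_dim} out of range [1, {p}]")
    if n_learners < 1:
        raise ValueError(f"n_learners must be >= 1; got {n_learners}")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} training samples")
    _check_metric(metric)
    mu = sigma = None
    if standardize:
        mu = values.mean(axis=0)
        sigma = values.std(axis=0, ddof=0)
        sigma = np.where(sigma > 0, sigma, 1.0)
        values = (values - mu) / sigma
    streams = np.random.SeedSequence(seed).spawn(n_learners)
    subspaces = [
        np.sort(np.random.default_rng(s).choice(p, size=subspace_dim, replace=False))
        for s in streams
    ]
    return RSKNNModel(
        train_X=np.ascontiguousarray(values), train_labels=labels,
        subspaces=subspaces, n_learners=n_learners, k=k, metric=metric,
        seed=seed, standardize=standardize, mu=mu, sigma=sigma,
    )


def predict_ensemble(model: RSKNNModel, queries) -> tuple[np.ndarray, np.ndarray]:
    """Predict classes for a batch of query rows.

    Each learner casts one vote: its subspace-restricted k-NN class.  The
    final class is the modal vote; the returned vote fractions (one row per
    query, summing to 1 over classes) serve as scores for one-vs-all ROC.
    """
    q = queries.values if hasattr(queries, "values") else np.asarray(queries, dtype=np.float64)
    if q.ndim == 1:
        q = q[None, :]
    if q.shape[1] != model.train_X.shape[1]:
        raise ValueError(
            f"query has {q.shape[1]} features, model expects {model.train_X.shape[1]}"
        )
    if model.standardize:
        q = (q - model.mu) / model.sigma
    n_q = q.shape[0]
    nc = model.n_classes
    sp_metric = _check_metric(model.metric)
    votes = np.zeros((n_q, nc), dtype=np.int64)
    dist_agg = np.zeros((n_q, nc))  # summed neighbour distance, ensemble tie-break
    for sub in model.subspaces:
        d = cdist(q[:, sub], model.train_X[:, sub], metric=sp_metric)
        nn = np.argsort(d, axis=1, kind="stable")[:, : model.k]
        for i in range(n_q):
            winner, _, dsum = _vote(d[i, nn[i]], model.train_labels[nn[i]], nc)
            votes[i, winner] += 1
            finite = np.isfinite(dsum)
            dist_agg[i, finite] += dsum[finite]
    pred = np.empty(n_q, dtype=np.int64)
    for i in range(n_q):
        top = votes[i].max()
        tied = np.flatnonzero(votes[i] == top)
        pred[i] = int(tied[np.lexsort((tied, dist_agg[i, tied]))[0]])
    fractions = votes / model.n_learners
    return pred, fractions


def default_k_grid(n_train: int) -> np.ndarray:
    """Unique rounded powers spanning 1 to n/2 (evenly spaced in log)."""
    hi = max(n_train // 2, 1)
    grid = np.unique(np.round(np.geomspace(1, hi, num=10)).astype(int))
    return grid[grid >= 1]


def tune_k(
    X,
    labels=None,
    k_grid=None,
    cv_folds: int = 10,
    metric: str = "euclidean",
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose k for the k-NN base learner by stratified cross-validation.

    Evaluates plain k-NN error over ``k_grid`` (default: log-spaced from 1
    to n/2); returns ``(best k, error curve)`` with ties going to the
    smallest k.
    """
    from .evaluation import stratified_folds

    values = X.values if hasattr(X, "values") else np.asarray(X, dtype=np.float64)
    if labels is None:
        labels = X.labels
    labels = np.asarray(labels, dtype=np.int64)
    n = values.shape[0]
    if k_grid is None:
        k_grid = default_k_grid(n)
    k_grid = np.asarray(k_grid, dtype=int)
    if k_grid.size == 0:
        raise ValueError("empty k grid")
    folds = stratified_folds(labels, cv_folds, seed=seed)
    min_train = min(n - int((folds == f).sum()) for f in range(cv_folds))
    if k_grid.max() > min_train:
        raise ValueError(
            f"k grid maximum {k_grid.max()} exceeds smallest training fold {min_train}"
        )
    errors = np.zeros(k_grid.size)
    sp_metric = _check_metric(metric)
    for f in range(cv_folds):
        test = folds == f
        d = cdist(values[test], values[~test], metric=sp_metric)
        order = np.argsort(d, axis=1, kind="stable")
        y_tr = labels[~test]
        nc = int(labels.max()) + 1
        for gi, k in enumerate(k_grid):
            wrong = 0
            for i in range(d.shape[0]):
                nn = order[i, :k]
                winner, _, _ = _vote(d[i, nn], y_tr[nn], nc)
                wrong += winner != labels[test][i]
            errors[gi] += wrong
    errors /= n
    best = int(k_grid[np.argmin(errors)])
    return best, errors
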