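"""CART trees, a bagged random forest, and out-of-bag permutation importance.

The forest here is not the pipeline's classifier — it is the feature
*selector*.  Each tree is grown on a bootstrap resample; the samples a tree
never saw (its out-of-bag set, on average ~36.8% of the data) give an
unbiased error estimate.  Permutation importance asks: how much does the
tree's OOB error rise when one feature's values are shuffled, destroying
any association with the label while preserving the marginal distribution?

Per tree t and split-used feature j:

    d_tj = eps_tj - eps_t        (OOB error after minus before permuting j)

with d_tj = 0 for features the tree never splits on.  Importance is the
per-feature mean of d_tj over trees, standardized by its standard
deviation: VI_j = d_mean_j / d_sd_j (or the raw mean where the SD is zero).
Higher means more important.  Ranking features by VI and sweeping the
top-j prefix against a cross-validated accuracy callback yields the
selected feature subset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------- impurity

def entropy(class_counts) -> float:
    """Shannon entropy in bits of a class-count vector: -sum p log2 p."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("entropy of empty/all-zero counts is undefined")
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def gini(class_counts) -> float:
    """Gini diversity index of a class-count vector: 1 - sum p^2."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("gini of empty/all-zero counts is undefined")
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    p = counts / counts.sum()
    return float(1.0 - (p * p).sum())


def _impurity_curves(sorted_labels: np.ndarray, n_classes: int, criterion: str):
    """Weighted child impurity for every split position of a sorted column.

    Position i splits the first i samples left, the rest right
    (i = 1..n-1).  Returns an array of length n-1 holding
    (n_L * imp_L + n_R * imp_R) / n for each position.
    """
    n = sorted_labels.shape[0]
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), sorted_labels] = 1.0
    left = np.cumsum(onehot, axis=0)[:-1]          # counts left of each position
    total = left[-1] + onehot[-1]
    right = total - left
    nl = np.arange(1, n, dtype=np.float64)
    nr = n - nl
    with np.errstate(divide="ignore", invalid="ignore"):
        pl = left / nl[:, None]
        pr = right / nr[:, None]
        if criterion == "gini":
            il = 1.0 - (pl * pl).sum(axis=1)
            ir = 1.0 - (pr * pr).sum(axis=1)
        else:  # entropy
            logl = np.log2(pl, out=np.zeros_like(pl), where=pl > 0)
            logr = np.log2(pr, out=np.zeros_like(pr), where=pr > 0)
            il = -(pl * logl).sum(axis=1)
            ir = -(pr * logr).sum(axis=1)
    return (nl * il + nr * ir) / n


# ---------------------------------------------------------------- trees

@dataclass
class TreeNode:
    """One node of a CART tree.

    Internal nodes carry ``split_feature``/``split_threshold`` and two
    children; leaves carry the class-count distribution of the samples that
    reached them.  ``x <= threshold`` goes left.
    """

    impurity: float
    class_counts: np.ndarray
    split_feature: int | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    def predict_one(self, x: np.ndarray) -> int:
        node = self
        while not node.is_leaf:
            node = node.left if x[node.split_feature] <= node.split_threshold else node.right
        return int(np.argmax(node.class_counts))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.predict_one(row) for row in np.asarray(X)], dtype=np.int64)

    def split_features_used(self) -> set[int]:
        if self.is_leaf:
            return set()
        return {self.split_feature} | self.left.split_features_used() | self.right.split_features_used()


def _best_split(X, y, idx, features, n_classes, criterion):
    """Best (feature, threshold, weighted-child-impurity) over candidates.

    Thresholds are midpoints of consecutive sorted unique values; impurity
    ties break to the lowest feature index then the lowest threshold, which
    the ordered scan delivers for free with strict improvement checks.
    """
    best = None  # (impurity, feature, threshold)
    for f in features:
        col = X[idx, f]
        order = np.argsort(col, kind="stable")
        sc = col[order]
        sl = y[idx][order]
        distinct = np.flatnonzero(sc[1:] > sc[:-1])  # split positions after i
        if distinct.size == 0:
            continue
        curve = _impurity_curves(sl, n_classes, criterion)
        pos = distinct + 1  # number of samples left of the split
        imps = curve[pos - 1]
        j = int(np.argmin(imps))
        imp = float(imps[j])
        thr = 0.5 * (sc[pos[j] - 1] + sc[pos[j]])
        if best is None or imp < best[0] - 1e-12:
            best = (imp, int(f), float(thr))
    return best


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    sample_idx: np.ndarray | None = None,
    criterion: str = "gini",
    max_splits: int | None = None,
    max_features: int | None = None,
    min_leaf: int = 1,
    rng: np.random.Generator | None = None,
) -> TreeNode:
    """Grow one CART tree on ``X[sample_idx]``.

    Splits greedily maximise impurity decrease; growth stops at purity,
    ``min_leaf``, a shared ``max_splits`` budget, or when no feature varies.
    ``max_features`` (if set) subsamples candidate features at *each split*
    via ``rng`` — the random-forest ingredient.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if criterion not in ("gini", "entropy"):
        raise ValueError(f"criterion must be gini or entropy; got {criterion!r}")
    if sample_idx is None:
        sample_idx = np.arange(X.shape[0])
    sample_idx = np.asarray(sample_idx, dtype=np.intp)
    if sample_idx.size < 1 or X.shape[1] < 1:
        raise ValueError("need >= 1 sample and >= 1 feature")
    n_classes = int(y.max()) + 1
    imp_fn = gini if criterion == "gini" else entropy
    budget = [math.inf if max_splits is None else int(max_splits)]
    p = X.shape[1]
    if rng is None:
        rng = np.random.default_rng(0)

    def build(idx: np.ndarray) -> TreeNode:
        counts = np.bincount(y[idx], minlength=n_classes).astype(np.float64)
        node = TreeNode(impurity=imp_fn(counts), class_counts=counts)
        if node.impurity <= 0 or idx.size < 2 * min_leaf or budget[0] <= 0:
            return node
        if max_features is not None and max_features < p:
            feats = np.sort(rng.choice(p, size=max_features, replace=False))
        else:
            feats = np.arange(p)
        found = _best_split(X, y, idx, feats, n_classes, criterion)
        if found is None or found[0] >= node.impurity - 1e-12:
            return node
        _, f, thr = found
        mask = X[idx, f] <= thr
        if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
            return node
        budget[0] -= 1
        node.split_feature = f
        node.split_threshold = thr
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    return build(sample_idx)


# ---------------------------------------------------------------- forest

@dataclass
class ForestModel:
    """Bagged ensemble of CART trees with recorded OOB bookkeeping."""

    trees: list[TreeNode]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    ntree: int
    rng_seed: int
    criterion: str = "gini"
    n_classes: int = 2

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote over trees (ties to the lowest class index)."""
        votes = np.zeros((np.asarray(X).shape[0], self.n_classes))
        for tree in self.trees:
            pred = tree.predict(X)
            votes[np.arange(votes.shape[0]), pred] += 1
        return votes.argmax(axis=1)

    def oob_error(self, X: np.ndarray, y: np.ndarray) -> float:
        """Aggregate OOB misclassification rate (vote over trees per sample)."""
        X = np.asarray(X)
        y = np.asarray(y)
        votes = np.zeros((X.shape[0], self.n_classes))
        for tree, oob in zip(self.trees, self.oob_indices):
            if oob.size:
                pred = tree.predict(X[oob])
                votes[oob, pred] += 1
        seen = votes.sum(axis=1) > 0
        if not seen.any():
            raise ValueError("no sample is out-of-bag for any tree")
        return float((votes[seen].argmax(axis=1) != y[seen]).mean())


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    ntree: int = 100,
    criterion: str = "gini",
    max_splits: int | None = 359,
    seed: int = 0,
    max_features: int | None = None,
) -> ForestModel:
    """Fit a random forest of ``ntree`` CART trees on bootstrap resamples.

    Each bootstrap draws n samples with replacement; per-split candidate
    features default to ceil(sqrt(p)).  Tree t's RNG is an independent
    substream of ``seed`` so results do not depend on growth order.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if ntree < 1:
        raise ValueError(f"ntree must be >= 1; got {ntree}")
    n, p = X.shape
    if max_features is None:
        max_features = int(math.ceil(math.sqrt(p)))
    n_classes = int(y.max()) + 1
    trees, boots, oobs = [], [], []
    streams = np.random.SeedSequence(seed).spawn(ntree)
    for t in range(ntree):
        rng = np.random.default_rng(streams[t])
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = grow_tree(
            X, y, sample_idx=boot, criterion=criterion, max_splits=max_splits,
            max_features=max_features, rng=rng,
        )
        trees.append(tree)
        boots.append(boot)
        oobs.append(oob)
    return ForestModel(
        trees=trees, bootstrap_indices=boots, oob_indices=oobs,
        ntree=ntree, rng_seed=seed, criterion=criterion, n_classes=n_classes,
    )


# ------------------------------------------------- permutation importance

@dataclass
class ImportanceRanking:
    """Per-feature OOB permutation importance with error-difference provenance.

    ``vi`` is the standardized importance (mean error difference over its
    SD, or the raw mean where the SD is zero); ``order`` sorts features by
    decreasing importance (ties to the lowest index).  Features never used
    in any tree have importance exactly 0.
    """

    vi: np.ndarray
    d_mean: np.ndarray
    d_sd: np.ndarray
    order: np.ndarray
    n_trees_used: int = 0

    def to_table(self) -> str:
        lines = ["feature\td_mean\td_sd\timportance\trank"]
        rank = np.empty_like(self.order)
        rank[self.order] = np.arange(1, self.order.size + 1)
        for j in range(self.vi.size):
            lines.append(
                f"{j}\t{self.d_mean[j]:.6g}\t{self.d_sd[j]:.6g}\t{self.vi[j]:.6g}\t{rank[j]}"
            )
        return "\n".join(lines) + "\n"


def oob_permutation_importance(
    model: ForestModel,
    X: np.ndarray,
    y: np.ndarray,
    standardize: bool = True,
) -> ImportanceRanking:
    """OOB permutation importance of every feature under a fitted forest.

    Per tree t: compute the OOB error eps_t; for each feature j the tree
    splits on, permute column j over the OOB rows (dedicated per-(tree,
    feature) RNG stream derived from the forest seed), re-predict, and
    record d_tj = eps_tj - eps_t; d_tj = 0 for unused features.  Importance
    is mean(d_tj)/sd(d_tj) when ``standardize`` (sd > 0), else the plain
    per-tree mean d_tj, which is the per-tree-weighted OOB error-difference
    average.  Trees with an empty OOB set are skipped with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n, p = X.shape
    diffs = []
    skipped = 0
    for t, (tree, oob) in enumerate(zip(model.trees, model.oob_indices)):
        if oob.size == 0:
            skipped += 1
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        base_err = float((tree.predict(X_oob) != y_oob).mean())
        row = np.zeros(p)
        for j in sorted(tree.split_features_used()):
            rng = np.random.default_rng(
                np.random.SeedSequence(model.rng_seed, spawn_key=(1, t, j))
            )
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(oob.size), j]
            perm_err = float((tree.predict(X_perm) != y_oob).mean())
            row[j] = perm_err - base_err
        diffs.append(row)
    if skipped:
        warnings.warn(
            f"{skipped} tree(s) had no out-of-bag samples and were skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    if not diffs:
        raise ValueError("no tree had out-of-bag samples; cannot estimate importance")
    D = np.vstack(diffs)
    d_mean = D.mean(axis=0)
    d_sd = D.std(axis=0, ddof=1) if D.shape[0] > 1 else np.zeros(p)
    if standardize:
        vi = np.where(d_sd > 0, np.divide(d_mean, np.where(d_sd > 0, d_sd, 1.0)), d_mean)
    else:
        vi = d_mean.copy()
    order = np.argsort(-vi, kind="stable")
    return ImportanceRanking(
        vi=vi, d_mean=d_mean, d_sd=d_sd, order=order, n_trees_used=D.shape[0]
    )


# ---------------------------------------------------------------- selection

def select_features(
    X,
    ranking: ImportanceRanking,
    evaluator,
    tolerance: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Sweep top-j feature prefixes in importance order; pick the smallest
    adequate j.

    ``evaluator(values, labels) -> accuracy`` (fraction in [0, 1], typically
    cross-validated) is called for every prefix j = 1..p; the selected
    subset is the smallest j whose accuracy reaches (max accuracy -
    tolerance).  Returns ``(selected feature indices, accuracy curve)``;
    the curve has one entry per j with no gaps.
    """
    values = X.values if hasattr(X, "values") else np.asarray(X)
    labels = X.labels if hasattr(X, "labels") else None
    p = values.shape[1]
    if ranking.vi.size != p:
        raise ValueError(
            f"ranking covers {ranking.vi.size} features, matrix has {p}"
        )
    curve = np.empty(p)
    for j in range(1, p + 1):
        cols = ranking.order[:j]
        curve[j - 1] = evaluator(values[:, cols], labels)
    best = float(curve.max())
    j_sel = int(np.argmax(curve >= best - tolerance)) + 1
    return ranking.order[:j_sel].copy(), curve
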