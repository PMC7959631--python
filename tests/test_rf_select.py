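import numpy as np
import pytest

from ersknn import (
    entropy,
    fit_forest,
    generate_feature_table,
    gini,
    grow_tree,
    oob_permutation_importance,
    select_features,
)


class TestImpurity:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 5), 1.0), ((10, 0), 0.0), ((1, 1, 1, 1), 2.0), ((3, 1), 0.8112781244591328)],
    )
    def test_entropy_closed_forms(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "counts,expected", [((10, 0), 0.0), ((5, 5), 0.5), ((1, 1, 1, 1), 0.75)]
    )
    def test_gini_closed_forms(self, counts, expected):
        assert gini(counts) == pytest.approx(expected, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 6)
            counts = rng.integers(0, 20, size=k)
            if counts.sum() == 0:
                continue
            assert 0 <= entropy(counts) <= np.log2(k) + 1e-12
            assert 0 <= gini(counts) <= 1 - 1 / k + 1e-12

    @pytest.mark.parametrize("fn", [entropy, gini])
    def test_empty_counts_rejected(self, fn):
        with pytest.raises(ValueError):
            fn((0, 0))


def exhaustive_best_stump(X, y):
    """Oracle: enumerate every (feature, midpoint threshold) split."""
    best = (np.inf, None, None)
    n = y.size
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            left = X[:, f] <= thr
            imp = (left.sum() * gini(np.bincount(y[left], minlength=2))
                   + (~left).sum() * gini(np.bincount(y[~left], minlength=2))) / n
            if imp < best[0] - 1e-12:
                best = (imp, f, thr)
    return best


class TestGrowTree:
    def test_separable_1d_single_split(self):
        X = np.array([[-3.0], [-2.0], [-1.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        tree = grow_tree(X, y)
        assert not tree.is_leaf
        assert -1.0 < tree.split_threshold < 1.0
        assert tree.left.is_leaf and tree.right.is_leaf
        assert gini(tree.left.class_counts) == 0
        assert gini(tree.right.class_counts) == 0

    def test_pure_labels_single_leaf(self):
        X = np.arange(10, dtype=float)[:, None]
        tree = grow_tree(X, np.zeros(10, dtype=int))
        assert tree.is_leaf

    @pytest.mark.parametrize("criterion", ["gini", "entropy"])
    def test_zero_training_error_on_distinct_points(self, criterion):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 2))
        y = rng.integers(0, 2, size=20)
        tree = grow_tree(X, y, criterion=criterion)
        assert (tree.predict(X) == y).mean() == 1.0

    def test_first_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            X = rng.standard_normal((30, 3))
            y = (X[:, trial % 3] + 0.3 * rng.standard_normal(30) > 0).astype(int)
            tree = grow_tree(X, y, max_splits=1)
            imp, f, thr = exhaustive_best_stump(X, y)
            assert tree.split_feature == f
            assert tree.split_threshold == pytest.approx(thr)

    def test_max_splits_budget(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 2))
        y = rng.integers(0, 2, size=50)
        tree = grow_tree(X, y, max_splits=3)

        def count_splits(node):
            if node.is_leaf:
                return 0
            return 1 + count_splits(node.left) + count_splits(node.right)

        assert count_splits(tree) <= 3

    def test_children_partition_parent(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 2))
        y = rng.integers(0, 3, size=40)
        tree = grow_tree(X, y)

        def walk(node):
            if node.is_leaf:
                return
            assert node.class_counts.sum() == (
                node.left.class_counts.sum() + node.right.class_counts.sum()
            )
            walk(node.left)
            walk(node.right)

        walk(tree)


class TestForest:
    def test_oob_complements_bootstrap(self):
        fm, _ = generate_feature_table(2, 2, 40, 1.0, seed=0)
        model = fit_forest(fm.values, fm.labels, ntree=1, seed=7)
        boot, oob = model.bootstrap_indices[0], model.oob_indices[0]
        assert boot.size == 40
        union = np.union1d(np.unique(boot), oob)
        np.testing.assert_array_equal(union, np.arange(40))
        assert np.intersect1d(np.unique(boot), oob).size == 0

    def test_same_seed_identical_forests(self):
        fm, _ = generate_feature_table(2, 2, 60, 1.0, seed=1)
        m1 = fit_forest(fm.values, fm.labels, ntree=5, seed=3)
        m2 = fit_forest(fm.values, fm.labels, ntree=5, seed=3)
        for b1, b2 in zip(m1.bootstrap_indices, m2.bootstrap_indices):
            np.testing.assert_array_equal(b1, b2)
        np.testing.assert_array_equal(m1.predict(fm.values), m2.predict(fm.values))

    def test_separable_data_low_oob_error(self):
        fm, _ = generate_feature_table(4, 4, 200, 3.0, seed=2)
        model = fit_forest(fm.values, fm.labels, ntree=30, seed=5)
        assert model.oob_error(fm.values, fm.labels) < 0.10

    def test_oob_error_improves_with_ensemble_size(self):
        # weak trend over seeds: 50 trees never lose to 1 tree on average
        diffs = []
        for seed in range(5):
            fm, _ = generate_feature_table(4, 4, 120, 2.0, seed=seed)
            e1 = fit_forest(fm.values, fm.labels, ntree=1, seed=seed).oob_error(
                fm.values, fm.labels
            )
            e50 = fit_forest(fm.values, fm.labels, ntree=50, seed=seed).oob_error(
                fm.values, fm.labels
            )
            diffs.append(e1 - e50)
        assert np.mean(diffs) >= 0

    def test_ntree_validation(self):
        fm, _ = generate_feature_table(2, 2, 20, 1.0, seed=3)
        with pytest.raises(ValueError, match="ntree"):
            fit_forest(fm.values, fm.labels, ntree=0)


class TestPermutationImportance:
    def test_unused_feature_importance_exactly_zero(self):
        # a constant column can never be split on
        fm, _ = generate_feature_table(2, 1, 80, 2.0, seed=4)
        values = fm.values.copy()
        values[:, 2] = 0.0
        model = fit_forest(values, fm.labels, ntree=20, seed=1)
        ranking = oob_permutation_importance(model, values, fm.labels)
        assert ranking.vi[2] == 0.0
        assert ranking.d_mean[2] == 0.0

    def test_null_feature_centred_at_zero(self):
        # label-independent feature: mean error difference within 2 SE of 0,
        # SE taken over independent dataset replicates (per-tree differences
        # are correlated within a dataset)
        reps = []
        for seed in range(10):
            fm, _ = generate_feature_table(1, 1, 150, 2.0, seed=400 + seed)
            model = fit_forest(fm.values, fm.labels, ntree=60, seed=seed)
            ranking = oob_permutation_importance(model, fm.values, fm.labels)
            reps.append(ranking.d_mean[1])
        reps = np.array(reps)
        se = reps.std(ddof=1) / np.sqrt(reps.size)
        assert abs(reps.mean()) <= 2.5 * se

    def test_planted_feature_outranks_noise(self):
        fm, informative = generate_feature_table(1, 20, 200, 2.0, seed=6)
        model = fit_forest(fm.values, fm.labels, ntree=60, seed=3)
        ranking = oob_permutation_importance(model, fm.values, fm.labels)
        assert ranking.order[0] in informative

    def test_order_is_permutation(self):
        fm, _ = generate_feature_table(2, 6, 100, 1.5, seed=7)
        model = fit_forest(fm.values, fm.labels, ntree=20, seed=4)
        ranking = oob_permutation_importance(model, fm.values, fm.labels)
        np.testing.assert_array_equal(np.sort(ranking.order), np.arange(8))

    def test_raw_mean_flag_gives_eq_style_average(self):
        fm, _ = generate_feature_table(2, 2, 100, 2.0, seed=8)
        model = fit_forest(fm.values, fm.labels, ntree=30, seed=5)
        std = oob_permutation_importance(model, fm.values, fm.labels)
        raw = oob_permutation_importance(model, fm.values, fm.labels, standardize=False)
        np.testing.assert_allclose(raw.vi, std.d_mean)


class TestSelectFeatures:
    @staticmethod
    def _loo_nn_accuracy(values, labels):
        """Tiny evaluator: leave-one-out nearest-neighbour accuracy."""
        from scipy.spatial.distance import squareform, pdist

        d = squareform(pdist(values))
        np.fill_diagonal(d, np.inf)
        return float((labels[d.argmin(axis=1)] == labels).mean())

    def test_redundant_copies_collapse_to_one(self):
        rng = np.random.default_rng(9)
        base = np.r_[rng.standard_normal(50) - 2, rng.standard_normal(50) + 2]
        labels = np.r_[np.zeros(50, dtype=int), np.ones(50, dtype=int)]
        values = np.tile(base[:, None], (1, 5))
        model = fit_forest(values, labels, ntree=30, seed=6)
        ranking = oob_permutation_importance(model, values, labels)
        selected, curve = select_features(values, ranking, lambda v, _: self._loo_nn_accuracy(v, labels))
        assert selected.size == 1
        assert curve.size == 5

    def test_curve_has_no_gaps_and_selection_is_adequate(self):
        fm, informative = generate_feature_table(4, 16, 200, 2.0, seed=10)
        model = fit_forest(fm.values, fm.labels, ntree=60, seed=7)
        ranking = oob_permutation_importance(model, fm.values, fm.labels)
        selected, curve = select_features(
            fm, ranking, lambda v, y: self._loo_nn_accuracy(v, y)
        )
        assert curve.size == fm.n_features
        assert np.all(np.isfinite(curve))
        assert selected.size <= 8
        assert curve[selected.size - 1] >= curve.max() - 0.005

    def test_mismatched_ranking_rejected(self):
        fm, _ = generate_feature_table(2, 2, 40, 1.0, seed=11)
        model = fit_forest(fm.values[:, :3], fm.labels, ntree=5, seed=8)
        ranking = oob_permutation_importance(model, fm.values[:, :3], fm.labels)
        with pytest.raises(ValueError, match="ranking covers"):
            select_features(fm, ranking, lambda v, y: 1.0)
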