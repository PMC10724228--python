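import itertools

import numpy as np
import pytest

from polyrank import DESCRIPTOR_NAMES, DegradabilityTree, categorize_leaves, fit_tree
from polyrank.errors import ValidationError


def brute_force_best_split(X, y):
    """Oracle: exhaustive search over all (feature, integer threshold) splits."""
    parent = ((y - y.mean()) ** 2).sum()
    best = None
    for j in range(X.shape[1]):
        for thr in np.unique(X[:, j])[:-1]:
            mask = X[:, j] <= thr
            if mask.all() or not mask.any():
                continue
            sse = sum(((y[m] - y[m].mean()) ** 2).sum() for m in (mask, ~mask))
            gain = parent - sse
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, int(thr))
    return best


def random_counts(rng, n, d=9, high=5):
    return rng.integers(0, high, size=(n, d))


class TestFit:
    def test_constant_scores_single_leaf(self, rng):
        X = random_counts(rng, 12)
        tree = fit_tree(X, np.full(12, 0.7))
        assert tree.n_leaves_ == 1
        assert tree.leaves_[0].mean == pytest.approx(0.7)
        assert tree.predict(X) == pytest.approx(np.full(12, 0.7))

    def test_constant_descriptors_single_leaf_with_warning(self, rng):
        X = np.ones((8, 9), dtype=int)
        y = rng.normal(size=8)
        with pytest.warns(UserWarning, match="constant"):
            tree = fit_tree(X, y)
        assert tree.n_leaves_ == 1

    def test_ester_driven_scores_split_on_ester_first(self, rng):
        X = random_counts(rng, 30)
        y = X[:, 0].astype(float)  # score is exactly the ester count
        tree = fit_tree(X, y, max_leaves=10)
        gain, j, thr = brute_force_best_split(X, y)
        assert tree.tree_.feature == j == 0
        assert tree.tree_.threshold == thr
        # enough leaves -> every leaf pure in ester count
        n_values = np.unique(X[:, 0]).size
        tree_full = fit_tree(X, y, max_leaves=n_values)
        assert tree_full.n_leaves_ == n_values
        assert set(np.round(tree_full.leaf_means_, 9)) == set(np.unique(y))

    def test_every_internal_split_matches_oracle_at_root(self, rng):
        X = random_counts(rng, 25)
        y = rng.normal(size=25) + 2.0 * X[:, 4]
        tree = fit_tree(X, y, max_leaves=2)  # a single (root) split
        gain, j, thr = brute_force_best_split(X, y)
        assert (tree.tree_.feature, tree.tree_.threshold) == (j, thr)

    def test_leaf_mean_conservation(self, rng):
        X = random_counts(rng, 40)
        y = rng.normal(size=40)
        tree = fit_tree(X, y, max_leaves=8)
        weighted = sum(leaf.n * leaf.mean for leaf in tree.leaves_) / len(y)
        assert weighted == pytest.approx(y.mean())

    def test_row_permutation_invariance(self, rng):
        X = random_counts(rng, 30)
        y = rng.normal(size=30) + X[:, 1]
        tree_a = fit_tree(X, y, max_leaves=6)
        perm = rng.permutation(30)
        tree_b = fit_tree(X[perm], y[perm], max_leaves=6)

        def shape(node):
            if node.is_leaf:
                return ("leaf", round(node.mean, 12), node.n)
            return (node.feature, node.threshold, shape(node.left), shape(node.right))

        assert shape(tree_a.tree_) == shape(tree_b.tree_)

    def test_pruning_monotonicity(self, rng):
        X = random_counts(rng, 35)
        y = rng.normal(size=35) + X[:, 0] - 0.5 * X[:, 3]
        r2 = [
            fit_tree(X, y, max_leaves=k).score(X, y)
            for k in (1, 2, 4, 6, 8, 10)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_min_leaf_size_respected(self, rng):
        X = random_counts(rng, 20)
        y = rng.normal(size=20)
        tree = fit_tree(X, y, max_leaves=10, min_leaf_size=4)
        assert all(leaf.n >= 4 for leaf in tree.leaves_)


class TestExplain:
    def test_single_leaf_empty_path(self, rng):
        tree = fit_tree(random_counts(rng, 6), np.ones(6))
        assert tree.explain(np.zeros(9)) == []

    def test_ester_tree_path_is_ester_comparisons(self, rng):
        X = random_counts(rng, 30)
        y = X[:, 0].astype(float)
        tree = fit_tree(X, y, max_leaves=6)
        x = np.zeros(9)
        x[0] = 3
        path = tree.explain(x)
        assert path and all(feat == "ester" for feat, _, _ in path)
        depth = max(leaf.depth for leaf in tree.leaves_)
        assert len(path) <= depth

    def test_apply_routes_to_fitted_leaf(self, rng):
        X = random_counts(rng, 15)
        y = rng.normal(size=15) + X[:, 2]
        tree = fit_tree(X, y, max_leaves=4)
        leaf_ids = tree.apply(X)
        for leaf in tree.leaves_:
            assert set(leaf_ids[leaf.indices]) == {leaf.leaf_id}


class TestCategorize:
    def _tree_with_means(self, means, rng):
        # one leaf per distinct integer level of feature 0
        means = np.asarray(means, dtype=float)
        X = np.repeat(np.arange(len(means)), 2)[:, None] * np.ones((1, 9), dtype=int)
        y = np.repeat(means, 2)
        return fit_tree(X.astype(int), y, max_leaves=len(means))

    def test_three_singletons(self, rng):
        tree = self._tree_with_means([0.1, 0.5, 0.9], rng)
        rule = categorize_leaves(tree)
        assert rule.boundaries == pytest.approx((0.3, 0.7))
        cats = [rule.leaf_categories[leaf.leaf_id] for leaf in tree.leaves_]
        assert sorted(cats) == ["degradable", "middle", "undegradable"]

    def test_published_band_pattern(self, rng):
        # leaf means matching the three-band pattern (bands denser than the
        # band-to-band gaps): boundaries must fall inside the empty intervals
        means = [0.25, 0.29, 0.303, 0.421, 0.47, 0.52, 0.57, 0.62, 0.654, 0.716]
        tree = self._tree_with_means(means, rng)
        rule = categorize_leaves(tree)
        b1, b2 = rule.boundaries
        assert 0.303 < b1 < 0.421
        assert 0.654 < b2 < 0.716

    def test_clustered_means_recover_generating_partition(self, rng):
        centers = [0.1, 0.5, 0.9]
        means = sorted(
            c + dc for c in centers for dc in (-0.02, 0.0, 0.02)
        )
        tree = self._tree_with_means(means, rng)
        rule = categorize_leaves(tree)
        got = {}
        for leaf in tree.leaves_:
            got.setdefault(rule.leaf_categories[leaf.leaf_id], []).append(leaf.mean)
        # oracle: enumerate all 2-cut partitions, pick min within-group variance
        arr = np.array(means)
        best = min(
            (
                sum(((arr[a:b] - arr[a:b].mean()) ** 2).sum() for a, b in
                    ((0, i), (i, j), (j, len(arr)))),
                (i, j),
            )
            for i, j in itertools.combinations(range(1, len(arr)), 2)
        )[1]
        oracle_groups = [arr[: best[0]], arr[best[0]: best[1]], arr[best[1]:]]
        for label, oracle in zip(("undegradable", "middle", "degradable"), oracle_groups):
            assert sorted(np.round(got[label], 9)) == sorted(np.round(oracle, 9))

    def test_fewer_than_three_leaves_is_error(self, rng):
        tree = fit_tree(random_counts(rng, 6), np.ones(6))
        with pytest.raises(ValidationError, match="fallback"):
            categorize_leaves(tree)


class TestSerialization:
    def test_dict_and_text_renderings(self, rng):
        X = random_counts(rng, 20)
        y = rng.normal(size=20) + X[:, 0]
        tree = fit_tree(X, y, max_leaves=4)
        doc = tree.to_dict()
        assert doc["tree"]["feature"] in DESCRIPTOR_NAMES
        text = tree.render_text()
        assert "leaf" in text and "<=" in text
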