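"""CART trees: Gini, exhaustive split oracle, growth, regions, reports."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmmforest.tree import ClassificationTree, best_split, gini_impurity


def brute_force_best_split(X, y, n_classes, min_leaf=1):
    """Independent oracle: try every (dimension, midpoint) pair."""
    n, p = X.shape
    best = None
    for j in range(p):
        values = np.unique(X[:, j])
        for a, b in zip(values[:-1], values[1:]):
            s = 0.5 * (a + b)
            left = X[:, j] <= s
            nl, nr = left.sum(), n - left.sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            cl = np.bincount(y[left], minlength=n_classes)
            cr = np.bincount(y[~left], minlength=n_classes)
            cost = nl * gini_impurity(cl) + nr * gini_impurity(cr)
            if best is None or cost < best[0] - 1e-12:
                best = (cost, j, s)
    if best is None:
        return None
    parent = n * gini_impurity(np.bincount(y, minlength=n_classes))
    if parent - best[0] <= 1e-9:
        return None
    return best[1], best[2], parent - best[0]


class TestGini:
    def test_pure_node_zero(self):
        assert gini_impurity([10, 0]) == 0.0
        assert gini_impurity([0, 0, 7]) == 0.0

    def test_symmetric_two_class_half(self):
        assert gini_impurity([5, 5]) == pytest.approx(0.5)

    def test_nine_one(self):
        assert gini_impurity([9, 1]) == pytest.approx(0.18)

    def test_bounds(self):
        assert gini_impurity([1, 1, 1]) == pytest.approx(2.0 / 3.0)
        with pytest.raises(ValueError):
            gini_impurity([0, 0])
        with pytest.raises(ValueError):
            gini_impurity([-1, 2])


class TestBestSplit:
    def test_separable_1d_splits_at_straddling_midpoint(self):
        x = np.array([[0.1], [0.2], [0.4], [0.6], [0.8], [0.9]])
        y = np.array([0, 0, 0, 1, 1, 1])
        j, s, dec = best_split(x, y, 2)
        assert j == 0
        assert s == pytest.approx(0.5)
        assert dec == pytest.approx(6 * 0.5)  # root impurity fully removed

    def test_pure_node_returns_none(self):
        x = np.random.default_rng(0).random((20, 2))
        assert best_split(x, np.zeros(20, dtype=int), 2) is None

    def test_tie_breaks_to_lower_dimension(self):
        # identical coordinates in both columns: equal-cost splits
        x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([0, 0, 1, 1])
        j, s, _ = best_split(x, y, 2)
        assert j == 0
        assert s == pytest.approx(1.5)

    def test_min_leaf_respected(self):
        x = np.arange(10, dtype=float)[:, None]
        y = (np.arange(10) >= 1).astype(int)  # best unconstrained split at 0.5
        j, s, _ = best_split(x, y, 2, min_leaf=3)
        assert s >= 2.0  # both children must keep >= 3 samples

    def test_infinite_sentinel_routes_right(self):
        x = np.array([[1.0], [2.0], [np.inf], [np.inf]])
        y = np.array([0, 0, 1, 1])
        j, s, _ = best_split(x, y, 2)
        assert np.isfinite(s)
        assert (x[:, 0] <= s).sum() == 2

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(5, 60),
        p=st.integers(1, 3),
        k=st.integers(2, 3),
        seed=st.integers(0, 10_000),
    )
    def test_agrees_with_exhaustive_oracle(self, n, p, k, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((n, p)).round(2)  # ties included on purpose
        y = rng.integers(0, k, n)
        ours = best_split(X, y, k)
        oracle = brute_force_best_split(X, y, k)
        if oracle is None:
            assert ours is None
        else:
            assert ours is not None
            # equal cost; the chosen (j, s) may differ only between
            # equally-good splits
            assert ours[2] == pytest.approx(oracle[2], abs=1e-9)

    def test_oracle_agreement_larger_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(50, 200))
            p = int(rng.integers(1, 4))
            X = rng.random((n, p))
            y = (X[:, 0] + 0.3 * rng.random(n) > 0.6).astype(int)
            ours = best_split(X, y, 2)
            oracle = brute_force_best_split(X, y, 2)
            assert (ours is None) == (oracle is None)
            if ours is not None:
                assert ours[2] == pytest.approx(oracle[2], abs=1e-9)


def make_three_region_data(n=3000, seed=0):
    """Three classes separated at Y=0.4, then X=0.1 and X=0.7 below it."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, 2))
    y = np.where(
        X[:, 1] >= 0.4, 0, np.where(X[:, 0] < 0.1, 1, np.where(X[:, 0] < 0.7, 2, 1))
    )
    return X, y


class TestGrowTree:
    def test_recovers_known_partition(self):
        X, y = make_three_region_data()
        results = ClassificationTree(
            X, y, feature_names=["X", "Y"], bounds=(np.zeros(2), np.ones(2))
        ).fit(min_leaf=5)
        splits = [
            (results.feature_names[nd.feature], nd.threshold)
            for nd in results.nodes if nd.feature >= 0
        ]
        thresholds = dict()
        for name, s in splits:
            thresholds.setdefault(name, []).append(s)
        assert any(abs(s - 0.4) < 0.02 for s in thresholds["Y"])
        assert any(abs(s - 0.1) < 0.02 for s in thresholds["X"])
        assert any(abs(s - 0.7) < 0.02 for s in thresholds["X"])
        # conflict-free data grown to small leaves: zero training error
        assert np.mean(results.predict(X) == y) == 1.0

    def test_prediction_routes_to_constructed_region(self):
        X, y = make_three_region_data()
        results = ClassificationTree(X, y, feature_names=["X", "Y"]).fit(min_leaf=5)
        assert results.predict([[0.05, 0.2]])[0] == 1
        assert results.predict([[0.4, 0.2]])[0] == 2
        assert results.predict([[0.5, 0.9]])[0] == 0

    def test_min_leaf_n_gives_single_majority_leaf(self):
        X, y = make_three_region_data(n=200)
        results = ClassificationTree(X, y).fit(min_leaf=200)
        assert results.n_leaves == 1
        majority = np.bincount(y).argmax()
        assert (results.predict(X) == majority).all()

    def test_single_class_gives_single_pure_leaf(self):
        X = np.random.default_rng(1).random((50, 3))
        results = ClassificationTree(X, np.ones(50, dtype=int)).fit(min_leaf=1)
        assert results.n_leaves == 1
        assert results.nodes[0].impurity == 0.0

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            ClassificationTree(np.empty((0, 2)), np.empty(0))

    def test_split_never_increases_weighted_impurity(self):
        X, y = make_three_region_data(n=800, seed=3)
        results = ClassificationTree(X, y).fit(min_leaf=10)
        for node in results.nodes:
            if node.feature < 0:
                continue
            left, right = results.nodes[node.left], results.nodes[node.right]
            assert left.n + right.n == node.n
            parent_cost = node.n * node.impurity
            child_cost = left.n * left.impurity + right.n * right.impurity
            assert child_cost <= parent_cost + 1e-9

    def test_max_leaves_limits_size(self):
        X, y = make_three_region_data()
        results = ClassificationTree(X, y).fit(min_leaf=5, max_leaves=3)
        assert results.n_leaves == 3

    def test_leaves_tile_root_box(self):
        """Monte-Carlo membership: every point lands in exactly one leaf
        whose recorded bounds contain it (left-closed on the split)."""
        X, y = make_three_region_data(n=1000, seed=5)
        results = ClassificationTree(
            X, y, bounds=(np.zeros(2), np.ones(2))
        ).fit(min_leaf=20)
        rng = np.random.default_rng(11)
        pts = rng.random((500, 2))
        leaf_of = results.apply(pts)
        for pt, lid in zip(pts, leaf_of):
            hits = [
                i for i in results.leaf_ids
                if np.all(pt > results.nodes[i].bounds_lo - 1e-12)
                and np.all(pt <= results.nodes[i].bounds_hi + 1e-12)
            ]
            assert lid in hits
        # sample counts of leaves partition the training set
        assert sum(results.nodes[i].n for i in results.leaf_ids) == X.shape[0]

    def test_mean_gini_criterion_runs(self):
        X, y = make_three_region_data(n=400)
        results = ClassificationTree(X, y).fit(min_leaf=20, criterion="mean_gini")
        assert results.n_leaves >= 2


class TestRegionReport:
    def test_single_leaf_reports_global_rate(self):
        X, y = make_three_region_data(n=500)
        results = ClassificationTree(X, y).fit(min_leaf=500)
        report = results.region_report(y == 1)
        assert len(report) == 1
        assert report["space_pct"].iloc[0] == pytest.approx(100.0)
        assert report["density_pct"].iloc[0] == pytest.approx(100 * np.mean(y == 1))

    def test_shares_conserve(self):
        X, y = make_three_region_data(n=2000, seed=9)
        results = ClassificationTree(X, y).fit(min_leaf=50)
        report = results.region_report(y == 2)
        assert report["space_pct"].sum() == pytest.approx(100.0)
        assert report["share_pct"].sum() == pytest.approx(100.0)

    def test_json_and_dot_exports(self, tmp_path):
        X, y = make_three_region_data(n=300)
        results = ClassificationTree(X, y, feature_names=["X", "Y"]).fit(min_leaf=30)
        payload = json.loads(results.to_json())
        assert payload["feature_names"] == ["X", "Y"]
        assert payload["tree"]["n"] == 300
        dot = results.to_dot(positive=(y == 0))
        assert dot.startswith("digraph") and "->" in dot
        results.to_json(tmp_path / "tree.json")
        assert json.loads((tmp_path / "tree.json").read_text())["tree"]["n"] == 300

    def test_summary_mentions_structure(self):
        X, y = make_three_region_data(n=300)
        text = ClassificationTree(X, y).fit(min_leaf=30).summary()
        assert "leaves" in text and "importance" in text
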