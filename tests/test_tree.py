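import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hccdx.tree import (TreeParams, entropy, fit_tree, gain, gain_ratio,
                        load_tree, predict_tree, residual_entropy, save_tree,
                        split_info, tree_from_dict, tree_to_dict)


# -------------------------------------------------- independent oracles

def oracle_entropy(y):
    h = 0.0
    n = len(y)
    for c in (0, 1):
        p = sum(1 for v in y if v == c) / n
        if p > 0:
            h -= p * math.log2(p)
    return h


def oracle_split_scores(x, y, threshold):
    """Brute-force branch tallies for a binary threshold split."""
    left = [(xi, yi) for xi, yi in zip(x, y) if xi <= threshold]
    right = [(xi, yi) for xi, yi in zip(x, y) if xi > threshold]
    branches = [b for b in (left, right) if b]
    n = len(y)
    if len(branches) < 2:
        return 0.0, 0.0, 0.0
    res = sum(len(b) / n * oracle_entropy([yi for _, yi in b]) for b in branches)
    g = oracle_entropy(list(y)) - res
    si = -sum(len(b) / n * math.log2(len(b) / n) for b in branches)
    return res, g, (g / si if si > 0 else 0.0)


def oracle_best_split(X, y, criterion):
    """Exhaustive search over all features and candidate midpoints."""
    best = (-1.0, None, None)
    for j in range(X.shape[1]):
        vals = sorted(set(X[:, j]))
        for a, b in zip(vals, vals[1:]):
            thr = (a + b) / 2
            _, g, gr = oracle_split_scores(X[:, j], y, thr)
            score = gr if criterion == "gain_ratio" else g
            if score > best[0]:
                best = (score, j, thr)
    return best


# ---------------------------------------------------------------- entropy

class TestEntropy:
    def test_pure_labels(self):
        assert entropy([1, 1, 1]) == 0.0
        assert entropy([0]) == 0.0

    def test_even_split_is_one_bit(self):
        assert entropy([0, 1, 0, 1]) == pytest.approx(1.0)

    def test_hcc_class_balance(self):
        y = np.r_[np.zeros(63), np.ones(102)]
        assert entropy(y) == pytest.approx(0.9593, abs=1e-4)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            entropy([])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40))
    def test_bounds_and_oracle_agreement(self, y):
        h = entropy(y)
        assert 0.0 <= h <= 1.0 + 1e-12
        assert h == pytest.approx(oracle_entropy(y), abs=1e-12)


# ----------------------------------------------------------- split scores

class TestSplitCriteria:
    def test_feature_identical_to_labels_gains_full_entropy(self):
        y = np.array([0, 0, 1, 1, 1])
        assert gain(y.astype(float), y, 0.5) == pytest.approx(entropy(y))

    def test_single_branch_split_scores_zero(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        y = np.array([0, 1, 0, 1])
        assert gain(x, y, 5.0) == 0.0
        assert gain_ratio(x, y, 5.0) == 0.0

    def test_eight_row_fixture_matches_tally_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        y = np.array([0, 0, 1, 0, 1, 1, 1, 0])
        for thr in (1.5, 2.5, 3.5, 4.5, 5.5):
            res_o, g_o, gr_o = oracle_split_scores(x, y, thr)
            assert residual_entropy(x, y, thr) == pytest.approx(res_o, abs=1e-12)
            assert gain(x, y, thr) == pytest.approx(g_o, abs=1e-12)
            assert gain_ratio(x, y, thr) == pytest.approx(gr_o, abs=1e-12)

    def test_categorical_split_matches_oracle(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 2.0, 0.0])
        y = np.array([0, 0, 1, 1, 1, 0, 1, 0])
        branches = [[yi for xi, yi in zip(x, y) if xi == v] for v in (0, 1, 2)]
        n = len(y)
        res_o = sum(len(b) / n * oracle_entropy(b) for b in branches)
        assert residual_entropy(x, y, "categories") == pytest.approx(res_o, abs=1e-12)
        si_o = -sum(len(b) / n * math.log2(len(b) / n) for b in branches)
        assert split_info(x, "categories") == pytest.approx(si_o, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_gain_never_negative(self, data):
        n = data.draw(st.integers(4, 24))
        x = np.array(data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n)), float)
        y = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        thr = data.draw(st.floats(-0.5, 5.5))
        g = gain(x, y, thr)
        assert g >= -1e-12
        assert residual_entropy(x, y, thr) <= entropy(y) + 1e-12


# ------------------------------------------------------------------ trees

class TestFitTree:
    def test_separable_single_feature_is_depth_one(self, separable):
        X, y = separable
        tree = fit_tree(X, y, TreeParams(prune=False))
        assert tree.depth() == 1
        assert tree.feature == 0
        assert (predict_tree(tree, X) == y).all()

    def test_pure_labels_give_single_leaf(self):
        X = np.arange(8.0).reshape(-1, 1)
        tree = fit_tree(X, np.ones(8, dtype=int))
        assert tree.is_leaf
        assert tree.prediction == 1

    def test_root_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            X = rng.integers(0, 4, size=(12, 3)).astype(float)
            y = rng.integers(0, 2, size=12)
            if len(set(y)) < 2:
                continue
            for criterion in ("gain", "gain_ratio"):
                score, j, thr = oracle_best_split(X, y, criterion)
                tree = fit_tree(X, y, TreeParams(criterion=criterion,
                                                 min_leaf=1, prune=False))
                if score <= 1e-12:
                    assert tree.is_leaf
                else:
                    assert tree.feature == j
                    assert tree.threshold == pytest.approx(thr)

    def test_zero_features_gives_majority_leaf(self):
        tree = fit_tree(np.empty((5, 0)), np.array([1, 1, 1, 0, 0]))
        assert tree.is_leaf
        assert tree.prediction == 1

    def test_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_tree(np.empty((0, 2)), np.array([], dtype=int))

    def test_criteria_rank_identically_when_split_info_equal(self):
        # all features dichotomous and balanced: split_info = 1 bit for each,
        # so gain and gain ratio pick the same root
        rng = np.random.default_rng(8)
        half = np.r_[np.zeros(10), np.ones(10)]
        X = np.column_stack([rng.permutation(half) for _ in range(4)])
        y = X[:, 2].astype(int)          # feature 2 is perfectly informative
        t_gain = fit_tree(X, y, TreeParams(criterion="gain", prune=False))
        t_ratio = fit_tree(X, y, TreeParams(criterion="gain_ratio", prune=False))
        assert t_gain.feature == t_ratio.feature == 2

    def test_determinism_bit_identical(self, separable):
        X, y = separable
        a = fit_tree(X, y, TreeParams())
        b = fit_tree(X, y, TreeParams())
        assert tree_to_dict(a) == tree_to_dict(b)

    def test_leaf_counts_sum_to_training_rows(self, separable):
        X, y = separable

        def total(node):
            return node.n if node.is_leaf else sum(total(c) for c in node.children)

        tree = fit_tree(X, y, TreeParams(prune=False))
        assert total(tree) == len(y)


class TestPruning:
    def test_pruning_reduces_leaves_on_noisy_data(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(150, 4))
        y = rng.integers(0, 2, size=150)     # pure noise: nothing to learn
        grown = fit_tree(X, y, TreeParams(prune=False, min_leaf=1))
        pruned = fit_tree(X, y, TreeParams(prune=True, min_leaf=1))
        assert pruned.n_leaves() < grown.n_leaves()

    def test_pruning_keeps_genuine_structure(self, separable):
        X, y = separable
        pruned = fit_tree(X, y, TreeParams(prune=True))
        assert not pruned.is_leaf
        assert (predict_tree(pruned, X) == y).all()


class TestPredict:
    def test_single_leaf_predicts_constant(self):
        tree = fit_tree(np.zeros((4, 1)), np.array([1, 1, 1, 0]))
        assert tree.is_leaf
        assert (predict_tree(tree, np.array([[9.0], [-9.0]])) == 1).all()

    def test_training_rows_reproduced_by_unpruned_tree(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        tree = fit_tree(X, y, TreeParams(min_leaf=1, prune=False))
        assert (predict_tree(tree, X) == y).all()

    def test_unseen_category_routes_to_heaviest_child(self):
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 0, 1, 1])
        tree = fit_tree(X, y, TreeParams(min_leaf=1, prune=False),
                        feature_kinds=["qualitative"])
        assert not tree.is_leaf
        pred = predict_tree(tree, np.array([[7.0]]))
        assert pred[0] == 0          # routed to the 3-row branch


def test_serialization_round_trip(tmp_path, separable):
    X, y = separable
    tree = fit_tree(X, y, TreeParams())
    path = tmp_path / "tree.json"
    save_tree(tree, path)
    back = load_tree(path)
    assert tree_to_dict(back) == tree_to_dict(tree)
    np.testing.assert_array_equal(predict_tree(back, X), predict_tree(tree, X))
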