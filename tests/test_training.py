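"""Grid search, cutoff sweep, and tree-to-rules conversion."""

import numpy as np
import pytest

from aerd_phenotyper.features import FEATURES
from aerd_phenotyper.rules_engine import classify_matrix
from aerd_phenotyper.synthetic_corpus import uniform_labelled_counts
from aerd_phenotyper.training import (
    CUTOFF_EPS,
    HyperparameterGrid,
    grid_search_cart,
    select_encoding,
    sweep_cutoff,
    tree_to_rules,
)

SMALL_GRID = HyperparameterGrid(
    max_depth=(1, 2, 3, 4),
    min_samples_split=(2,),
    min_samples_leaf=(1, 5),
    max_features=(7,),
)


def traverse_tree(tree_spec, cutoff, X):
    """Independent oracle: walk the fitted tree arrays node by node."""
    t = tree_spec.estimator.tree_
    pos = list(tree_spec.estimator.classes_).index(1)
    out = []
    for row in np.asarray(X, dtype=float):
        node = 0
        while t.children_left[node] != -1:
            if row[t.feature[node]] <= t.threshold[node]:
                node = t.children_left[node]
            else:
                node = t.children_right[node]
        frac = t.value[node][0][pos] / t.value[node][0].sum()
        out.append(int(frac >= cutoff - CUTOFF_EPS))
    return np.array(out)


class TestGridSearch:
    def test_grid_enumerates_7000_configurations(self):
        assert len(HyperparameterGrid().configurations()) == 2 * 10 * 5 * 10 * 7

    def test_separable_single_feature_reaches_auc_one_at_depth_one(self):
        X = np.zeros((40, 7))
        X[:20, 0] = 5  # AERD count alone separates the classes
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        spec = grid_search_cart(X, y, SMALL_GRID)
        assert spec.train_auc == 1.0
        assert spec.max_depth == 1  # tie-break prefers the shallowest tree

    def test_single_class_labels_rejected(self):
        X = np.zeros((10, 7))
        with pytest.raises(ValueError):
            grid_search_cart(X, np.ones(10, int), SMALL_GRID)

    def test_deterministic_for_fixed_seed(self):
        X, y = uniform_labelled_counts(150, seed=3)
        a = grid_search_cart(X, y, SMALL_GRID)
        b = grid_search_cart(X, y, SMALL_GRID)
        assert a.params == b.params and a.train_auc == b.train_auc

    def test_subgrid_never_beats_full_grid(self):
        """Monotone grid restriction under in-sample selection."""
        X, y = uniform_labelled_counts(150, seed=3)
        sub = HyperparameterGrid(max_depth=(1, 2), min_samples_split=(2,),
                                 min_samples_leaf=(5,), max_features=(7,))
        assert grid_search_cart(X, y, sub).train_auc <= grid_search_cart(X, y, SMALL_GRID).train_auc


class TestSelectEncoding:
    def test_numeric_wins_when_counts_carry_the_signal(self, rng):
        """Class boundary at >6 mentions: presence/absence is useless."""
        n = 120
        X = np.zeros((n, 7))
        X[:, 4] = rng.integers(1, 13, n)  # all patients have the feature
        y = (X[:, 4] > 6.5).astype(int)
        Xb = (X > 0).astype(float)
        encoding, spec = select_encoding(X, Xb, y, SMALL_GRID)
        assert encoding == "numeric" and spec.train_auc == 1.0

    def test_tie_goes_to_numeric(self):
        X = np.zeros((40, 7))
        X[:20, 0] = 1
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        encoding, _ = select_encoding(X, X.copy(), y, SMALL_GRID)
        assert encoding == "numeric"

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            select_encoding(np.zeros((10, 7)), np.zeros((9, 7)), np.zeros(10))


class TestSweepCutoff:
    def test_scores_match_brute_force_confusion(self, rng):
        X, y = uniform_labelled_counts(200, seed=5)
        spec = grid_search_cart(X, y, SMALL_GRID)
        sweep = sweep_cutoff(spec, X, y)
        leaf = spec.leaf_scores(X)
        for c, s in zip(sweep.cutoffs, sweep.scores):
            pred = (leaf >= c - CUTOFF_EPS).astype(int)
            tp = ((pred == 1) & (y == 1)).sum()
            tn = ((pred == 0) & (y == 0)).sum()
            expected = (tp / (y == 1).sum() + tn / (y == 0).sum()) / 2
            assert s == pytest.approx(expected)

    def test_perfect_tree_ties_resolve_to_smallest_cutoff(self):
        X = np.zeros((40, 7))
        X[:20, 0] = 5
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        spec = grid_search_cart(X, y, SMALL_GRID)
        sweep = sweep_cutoff(spec, X, y)
        assert sweep.best_cutoff == 0.1
        assert all(s == 1.0 for s in sweep.scores[:-1] if s)  # pure leaves

    def test_cutoff_grid_is_tenths(self):
        X, y = uniform_labelled_counts(50, seed=2)
        spec = grid_search_cart(X, y, SMALL_GRID)
        sweep = sweep_cutoff(spec, X, y)
        assert sweep.cutoffs == [round(c / 10, 1) for c in range(1, 11)]
        assert sweep.best_cutoff in sweep.cutoffs


class TestTreeToRules:
    def test_rule_count_equals_leaf_count_and_path_lengths(self):
        X, y = uniform_labelled_counts(300, seed=8)
        spec = grid_search_cart(X, y, SMALL_GRID)
        rules = tree_to_rules(spec, 0.5)
        n_leaves = spec.estimator.get_n_leaves()
        assert len(rules.rules) == n_leaves
        assert all(len(r.conditions) <= spec.max_depth for r in rules.rules)

    def test_single_leaf_tree_gives_one_unconditional_rule(self):
        grid = HyperparameterGrid(max_depth=(1,), min_samples_split=(2,),
                                  min_samples_leaf=(1,), max_features=(7,))
        X = np.zeros((40, 7))  # constant features: no split is possible
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        spec = grid_search_cart(X, y, grid)
        rules = tree_to_rules(spec, 0.5)
        assert len(rules.rules) == 1
        assert rules.rules[0].conditions == []
        assert rules.rules[0].predicted_label == "Yes"  # leaf fraction 0.5 >= cutoff

    @pytest.mark.parametrize("cutoff", [0.1, 0.5, 0.6, 1.0])
    def test_rules_equal_tree_traversal_on_random_grid(self, cutoff, rng):
        X, y = uniform_labelled_counts(400, seed=13)
        spec = grid_search_cart(X, y, SMALL_GRID)
        rules = tree_to_rules(spec, cutoff)
        Xe = rng.integers(0, 13, size=(3000, 7))
        by_rules, _ = classify_matrix(Xe, rules)
        by_tree = traverse_tree(spec, cutoff, Xe)
        assert (by_rules == by_tree).all()

    def test_invalid_cutoff_rejected(self):
        X, y = uniform_labelled_counts(50, seed=2)
        spec = grid_search_cart(X, y, SMALL_GRID)
        with pytest.raises(ValueError):
            tree_to_rules(spec, 0.0)
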