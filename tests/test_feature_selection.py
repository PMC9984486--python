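import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtikit.feature_selection import (
    discretize,
    entropy,
    iwssr_select,
    make_nb_evaluator,
    make_tree_evaluator,
    rank_features,
    symmetric_uncertainty,
)

discrete_vectors = st.lists(st.integers(0, 4), min_size=2, max_size=60)


class TestEntropy:
    def test_uniform_binary(self):
        assert entropy([0, 1]) == 1.0

    def test_constant(self):
        assert entropy([1, 1, 1]) == 0.0

    def test_third_two_thirds(self):
        expected = -(1 / 3) * math.log2(1 / 3) - (2 / 3) * math.log2(2 / 3)
        assert math.isclose(entropy([0, 0, 1, 1, 1, 1]), expected)
        assert abs(entropy([0, 0, 1, 1, 1, 1]) - 0.9183) < 1e-4

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            entropy([])


class TestDiscretize:
    def test_midpoint_split(self):
        assert discretize([0, 1, 2, 3], bins=2).tolist() == [0, 0, 1, 1]

    def test_constant(self):
        assert discretize([5.0, 5.0, 5.0]).tolist() == [0, 0, 0]

    def test_binary_passthrough(self):
        codes = discretize([0, 1, 0, 1], bins=5)
        assert codes.tolist() == [0, 1, 0, 1]

    def test_bins_validation(self):
        with pytest.raises(ValueError):
            discretize([1, 2], bins=1)


class TestSymmetricUncertainty:
    def test_identical_is_one(self):
        f = np.array([0, 1, 0, 1, 1])
        assert symmetric_uncertainty(f, f) == 1.0

    def test_independent_is_zero(self):
        assert symmetric_uncertainty([0, 0, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_hand_computed(self):
        f = np.array([0, 0, 0, 1])
        c = np.array([0, 0, 1, 1])
        h_f = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        h_c = 1.0
        h_f_given_c = 0.5 * 0.0 + 0.5 * 1.0
        expected = 2 * (h_f - h_f_given_c) / (h_f + h_c)
        assert math.isclose(symmetric_uncertainty(f, c), expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            symmetric_uncertainty([0, 1], [0, 1, 0])

    @settings(max_examples=100, derandomize=True)
    @given(discrete_vectors, discrete_vectors)
    def test_symmetry_and_range(self, f, c):
        n = min(len(f), len(c))
        f, c = np.array(f[:n]), np.array(c[:n])
        su_fc = symmetric_uncertainty(f, c)
        su_cf = symmetric_uncertainty(c, f)
        assert math.isclose(su_fc, su_cf, abs_tol=1e-12)
        assert 0.0 <= su_fc <= 1.0


class TestRankFeatures:
    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        X = np.column_stack([rng.normal(size=100), y.astype(float), rng.normal(size=100)])
        assert rank_features(X, y).ranking[0] == 1

    def test_tie_broken_by_index(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        X = np.column_stack([col, col])
        ranking = rank_features(X, y).ranking
        assert ranking.tolist() == [0, 1]

    def test_permutation_property(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        weights = rank_features(X, y)
        assert sorted(weights.ranking.tolist()) == list(range(6))


def toy_joint_dataset():
    """Features 0,1 jointly predict y; feature 2 is a noisy label copy
    with high marginal SU; features 3-5 are noise."""
    rng = np.random.default_rng(42)
    n = 400
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    y = (a + b > 0).astype(int)
    c = (y ^ (rng.random(n) < 0.25)).astype(float)
    X = np.column_stack([a, b, c, rng.normal(size=(n, 3))])
    return X, y


class TestIwssr:
    def test_perfect_feature_scores_one(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        X = np.column_stack([rng.normal(size=(200, 3)), y.astype(float)])
        result = iwssr_select(X, y, seed=0)
        assert 3 in result.selected
        assert result.best_score == 1.0

    def test_accepted_scores_non_decreasing(self):
        X, y = toy_joint_dataset()
        result = iwssr_select(X, y, seed=0)
        accepted = [s for _, a, s in result.trace if a != "reject"]
        assert all(s2 >= s1 for s1, s2 in zip(accepted, accepted[1:]))

    def test_swap_excludes_high_su_proxy_matches_exhaustive(self):
        X, y = toy_joint_dataset()
        # the noisy label copy (feature 2) outranks a genuine feature
        ranking = rank_features(X, y).ranking.tolist()
        assert ranking.index(2) < ranking.index(0)
        evaluator = make_nb_evaluator(X, y, seed=0)
        result = iwssr_select(X, y, evaluator=evaluator, seed=0)
        assert 2 not in result.selected
        best_score, best_subset = max(
            (evaluator(list(s)), s)
            for r in (1, 2, 3)
            for s in itertools.combinations(range(X.shape[1]), r)
        )
        assert sorted(result.selected) == sorted(best_subset)
        assert math.isclose(result.best_score, best_score)

    def test_no_duplicates_and_bounded(self):
        X, y = toy_joint_dataset()
        result = iwssr_select(X, y, seed=1)
        assert len(result.selected) == len(set(result.selected))
        assert len(result.selected) <= X.shape[1]

    def test_needs_two_features(self):
        with pytest.raises(ValueError):
            iwssr_select(np.zeros((10, 1)), np.zeros(10, dtype=int))

    def test_evaluator_range_validated(self):
        X, y = toy_joint_dataset()
        with pytest.raises(ValueError, match="accuracy"):
            iwssr_select(X, y, evaluator=lambda s: 2.0)

    def test_deterministic(self):
        X, y = toy_joint_dataset()
        a = iwssr_select(X, y, seed=5)
        b = iwssr_select(X, y, seed=5)
        assert a.selected == b.selected and a.trace == b.trace


class TestEvaluators:
    def test_nb_evaluator_memoizes_and_scores(self):
        X, y = toy_joint_dataset()
        ev = make_nb_evaluator(X, y, seed=0)
        s1 = ev([0, 1])
        s2 = ev([1, 0])  # same subset, different order
        assert s1 == s2
        assert 0.0 <= s1 <= 1.0

    def test_nb_better_on_joint_pair_than_proxy(self):
        X, y = toy_joint_dataset()
        ev = make_nb_evaluator(X, y, seed=0)
        assert ev([0, 1]) > ev([2])

    def test_tree_evaluator_contract(self):
        X, y = toy_joint_dataset()
        ev = make_tree_evaluator(X, y, seed=0)
        score = ev([0, 1])
        assert 0.0 <= score <= 1.0
        assert ev([0, 1]) == score  # cached

    def test_tree_evaluator_subsamples_large_data(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(3000, 3))
        y = (X[:, 0] > 0).astype(int)
        ev = make_tree_evaluator(X, y, seed=0, max_rows=500)
        assert ev([0]) > 0.9
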