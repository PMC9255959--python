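"""Shapley estimator axioms, the exhaustive oracle, and the stability rule."""

from itertools import combinations
from math import factorial

import numpy as np
import pytest

from confoundcv import (
    AttributionMatrix,
    attribute,
    effect_direction,
    summarize_importance,
)


def exact_shapley(f, background, x):
    """Exhaustive interventional Shapley values by 2^d coalition enumeration."""
    d = background.shape[1]

    def value(S):
        A = background.copy()
        for j in S:
            A[:, j] = x[j]
        return float(np.mean(f(A)))

    phi = np.zeros(d)
    feats = list(range(d))
    for j in feats:
        others = [k for k in feats if k != j]
        for r in range(d):
            for S in combinations(others, r):
                w = factorial(r) * factorial(d - r - 1) / factorial(d)
                phi[j] += w * (value(S + (j,)) - value(S))
    return phi


class TestEstimator:
    def test_linear_model_is_exact(self):
        d = 5
        f = lambda A: 2.0 * A[:, 0]
        bg = np.zeros((10, d))
        x = np.zeros(d)
        x[0] = 1.0
        am = attribute(f, bg, x[None, :], seed=0)
        np.testing.assert_allclose(am.values[0], [2, 0, 0, 0, 0], atol=1e-12)

    def test_constant_model_attributes_nothing(self, rng):
        f = lambda A: np.full(A.shape[0], 3.3)
        am = attribute(f, rng.standard_normal((8, 4)), rng.standard_normal((3, 4)), seed=0)
        np.testing.assert_allclose(am.values, 0, atol=1e-12)

    def test_symmetry_of_duplicated_features(self, rng):
        # two exchangeable features, used jointly, with duplicated background
        # columns: the symmetry axiom forces equal credit
        f = lambda A: A[:, 0] * A[:, 1]
        bg = rng.standard_normal((20, 3))
        bg[:, 1] = bg[:, 0]
        x = np.array([[1.5, 1.5, 0.7]])
        am = attribute(f, bg, x, seed=1, n_orderings=20)
        assert am.values[0, 0] == pytest.approx(am.values[0, 1], abs=1e-10)

    def test_additivity_is_exact_for_nonlinear_models(self, rng):
        f = lambda A: np.tanh(A[:, 0] * A[:, 1]) + A[:, 2] ** 2
        bg = rng.standard_normal((15, 4))
        targets = rng.standard_normal((6, 4))
        am = attribute(f, bg, targets, seed=2)
        am.check_additivity(f(targets), tol=1e-10)

    def test_matches_exhaustive_enumeration_at_d6(self, rng):
        d = 6
        w = rng.standard_normal(d)

        def f(A):
            return A @ w + 0.8 * A[:, 0] * A[:, 1] + np.sin(A[:, 2])

        bg = rng.standard_normal((8, d))
        x = rng.standard_normal(d)
        exact = exact_shapley(f, bg, x)
        est = attribute(f, bg, x[None, :], seed=3, n_orderings=150).values[0]
        np.testing.assert_allclose(est, exact, atol=0.02)

    def test_deterministic_given_seed(self, rng):
        f = lambda A: A[:, 0] * A[:, 1]
        bg = rng.standard_normal((10, 3))
        t = rng.standard_normal((4, 3))
        a = attribute(f, bg, t, seed=9).values
        b = attribute(f, bg, t, seed=9).values
        np.testing.assert_array_equal(a, b)

    def test_empty_background_raises(self):
        with pytest.raises(ValueError):
            attribute(lambda A: A[:, 0], np.empty((0, 3)), np.zeros((1, 3)))

    def test_more_orderings_keep_top_feature(self, rng):
        """Stability monotonicity: a larger sampling budget never drops the
        top-ranked feature."""
        f = lambda A: 3.0 * A[:, 0] + 0.1 * A[:, 1] * A[:, 2]
        bg = rng.standard_normal((12, 5))
        t = rng.standard_normal((10, 5))
        for n_ord in (1, 8):
            am = attribute(f, bg, t, seed=4, n_orderings=n_ord)
            imp = np.abs(am.values).mean(axis=0)
            assert imp.argmax() == 0


def _runs_from(per_run_importance, n_subjects=4):
    """Build AttributionMatrix runs whose mean-|value| per feature is given."""
    runs = []
    for r, imp in enumerate(per_run_importance):
        values = np.tile(np.asarray(imp, dtype=float), (n_subjects, 1))
        runs.append(AttributionMatrix(values=values, base_value=0.0, run_seed=r))
    return runs


class TestStabilityRule:
    def test_hand_computed_example(self):
        # S̄_f = (0.6, 0.2, 0.1) each run -> S̄ = 0.3, threshold 0.6 inclusive
        runs = _runs_from([[0.6, 0.2, 0.1]] * 7)
        s = summarize_importance(runs)
        assert s.grand_mean == pytest.approx(0.3)
        assert list(s.stable_set) == [0]
        assert s.qualifying_runs[0] == 7

    def test_five_of_seven_is_excluded(self):
        hot = [0.9, 0.2, 0.1]
        cold = [0.3, 0.3, 0.3]
        runs = _runs_from([hot] * 5 + [cold] * 2)
        s = summarize_importance(runs)
        assert 0 not in s.stable_set  # 5 < required 6

    def test_six_of_seven_is_included(self):
        hot = [0.9, 0.2, 0.1]
        cold = [0.3, 0.3, 0.3]
        runs = _runs_from([hot] * 6 + [cold])
        s = summarize_importance(runs)
        assert 0 in s.stable_set
        assert s.required_runs == 6

    def test_uniform_importance_gives_empty_set(self):
        runs = _runs_from([[0.4, 0.4, 0.4]] * 7)
        assert summarize_importance(runs).stable_set.size == 0

    def test_threshold_scales_with_run_count(self):
        runs = _runs_from([[0.9, 0.1, 0.1]] * 3)
        assert summarize_importance(runs).required_runs == 3  # ceil(18/7)

    def test_inconsistent_feature_counts_raise(self):
        runs = _runs_from([[0.5, 0.5]])
        runs += _runs_from([[0.5, 0.5, 0.5]])
        with pytest.raises(ValueError):
            summarize_importance(runs)


class TestEffectDirection:
    def test_higher_and_lower(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        pred = np.array([0, 0, 1, 1])  # positives have the higher values
        assert effect_direction(X, pred, np.array([0])) == {0: "higher"}
        assert effect_direction(X, 1 - pred, np.array([0])) == {0: "lower"}

    def test_all_positive_is_degenerate(self):
        X = np.ones((4, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            out = effect_direction(X, np.ones(4, dtype=int), np.array([0]))
        assert out == {0: "undefined"}

    def test_no_positive_raises(self):
        with pytest.raises(ValueError):
            effect_direction(np.ones((4, 2)), np.zeros(4, dtype=int), np.array([0]))

    def test_empty_stable_set_raises(self):
        with pytest.raises(ValueError):
            effect_direction(np.ones((4, 2)), np.array([0, 1, 0, 1]), np.array([]))
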