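"""Metric oracle, splits, nested CV, permutation machinery, LOSO."""

import numpy as np
import pytest

from confoundcv import (
    CohortConfig,
    ConfoundFrame,
    CVPlan,
    ModelSpec,
    balanced_accuracy,
    bonferroni_adjust,
    fit_pipeline,
    generate_cohort,
    holdout_evaluate,
    leave_one_site_out,
    make_binary_labels,
    nested_cv,
    permutation_test,
    split_explore_holdout,
)


def brute_force_balanced_accuracy(y_true, y_pred):
    """Independent oracle: explicit per-class tally."""
    classes = sorted(set(y_true))
    recalls = []
    for cls in classes:
        hits = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        total = sum(1 for t in y_true if t == cls)
        recalls.append(hits / total)
    return sum(recalls) / len(recalls)


class TestBalancedAccuracy:
    def test_hand_arithmetic(self):
        assert balanced_accuracy([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(0.75)

    def test_perfect_prediction_any_sizes(self):
        y = [0] * 9 + [1]
        assert balanced_accuracy(y, y) == 1.0

    def test_constant_prediction_is_chance(self):
        assert balanced_accuracy([0, 0, 0, 1], [0, 0, 0, 0]) == 0.5

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            k = rng.integers(2, 9)
            n = rng.integers(2 * k, 80)
            y = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
            p = rng.integers(0, k, n)
            assert balanced_accuracy(y, p) == pytest.approx(
                brute_force_balanced_accuracy(list(y), list(p)), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import balanced_accuracy_score

        y = rng.integers(0, 3, 200)
        p = rng.integers(0, 3, 200)
        assert balanced_accuracy(y, p) == pytest.approx(balanced_accuracy_score(y, p))


class TestSplit:
    def test_partition_law_and_sizes(self, labeled_data):
        X, y, C = labeled_data
        idx = np.arange(y.size)
        ex, ho = split_explore_holdout(idx, y, C, CVPlan(seed=0))
        assert np.intersect1d(ex, ho).size == 0
        assert np.array_equal(np.sort(np.concatenate([ex, ho])), idx)
        assert abs(ho.size - 0.2 * y.size) <= 0.02 * y.size + 2

    def test_label_proportions_preserved(self):
        rng = np.random.default_rng(0)
        y = (rng.random(1000) < 0.35).astype(int)
        ex, ho = split_explore_holdout(np.arange(1000), y, None, CVPlan(seed=1))
        assert abs(y[ho].mean() - y[ex].mean()) < 0.02

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            split_explore_holdout(np.arange(10), np.zeros(10), None, CVPlan(seed=0))


class TestNestedCV:
    def test_outer_fold_sizes_at_n70(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((70, 5))
        y = np.r_[np.zeros(35), np.ones(35)].astype(int)
        spec = ModelSpec("logistic", hyper_grid=[{"C": 1.0}], seed=0)
        res = nested_cv(spec, X, y, None, CVPlan(outer_folds=7, inner_folds=5, seed=0))
        assert len(res.scores) == 7  # each outer test fold had exactly 10 subjects

    def test_grid_of_one_always_chosen(self, labeled_data):
        X, y, C = labeled_data
        spec = ModelSpec("logistic", hyper_grid=[{"C": 0.5}], seed=0)
        res = nested_cv(spec, X[:120], y[:120], C.subset(np.arange(120)),
                        CVPlan(outer_folds=3, inner_folds=2, seed=0))
        assert all(p == {"C": 0.5} for p in res.chosen_params)

    def test_label_leak_feature_hits_ceiling(self, rng):
        X = rng.standard_normal((140, 6))
        y = rng.integers(0, 2, 140)
        X = np.column_stack([X, y])  # a feature equal to the label
        spec = ModelSpec("logistic", hyper_grid=[{"C": 10.0}], seed=0)
        res = nested_cv(spec, X, y, None, CVPlan(outer_folds=3, inner_folds=2, seed=0))
        assert res.mean_score >= 0.95


class TestHoldout:
    def test_deterministic_family_has_zero_seed_spread(self, labeled_data):
        X, y, C = labeled_data
        ex, ho = split_explore_holdout(np.arange(y.size), y, C, CVPlan(seed=2))
        res, _ = holdout_evaluate(
            "logistic", {"C": 1.0}, X[ex], y[ex], C.subset(ex),
            X[ho], y[ho], C.subset(ho), n_seeds=3, correction="none",
        )
        # no resampling and a deterministic solver: identical refits
        assert res.sd_score == 0.0

    def test_overlapping_indices_rejected(self, labeled_data):
        X, y, C = labeled_data
        with pytest.raises(ValueError):
            holdout_evaluate(
                "logistic", {}, X, y, C, X, y, C,
                explore_indices=np.arange(10), holdout_indices=np.arange(5, 15),
            )

    def test_pure_noise_cohort_sits_at_chance(self, rng):
        scores = []
        for rep in range(8):
            r = np.random.default_rng(rep)
            X = r.standard_normal((150, 10))
            y = r.integers(0, 2, 150)
            res, _ = holdout_evaluate(
                "logistic", {"C": 1.0}, X[:100], y[:100], None, X[100:], y[100:], None,
                n_seeds=1,
            )
            scores.append(res.mean_score)
        m = np.mean(scores)
        assert abs(m - 0.5) < 2 * np.std(scores) + 0.02


class TestPermutation:
    def test_add_one_formula(self):
        # observed beats all 999 nulls -> p = 1/1000
        calls = iter([1.0] + [0.0] * 999)

        def ev(y):
            return next(calls)

        _, p, null = permutation_test(ev, np.arange(10), n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_observed_at_null_median(self):
        vals = iter([0.5] + [i / 198 for i in range(199)])

        def ev(y):
            return next(vals)

        _, p, _ = permutation_test(ev, np.arange(10), n_perm=199, seed=0)
        assert 0.4 < p < 0.6

    def test_train_labels_only_are_shuffled(self):
        seen = []

        def ev(y_tr):
            seen.append(y_tr.copy())
            return 0.0

        y = np.arange(20)
        permutation_test(ev, y, n_perm=5, seed=0)
        assert np.array_equal(seen[0], y)  # observed call untouched
        for s in seen[1:]:
            assert sorted(s) == list(y) and not np.array_equal(s, y)

    def test_nperm_must_be_positive(self):
        with pytest.raises(ValueError):
            permutation_test(lambda y: 0.0, np.arange(4), n_perm=0)


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01, 0.04, 0.2]), [0.03, 0.12, 0.6])
        np.testing.assert_allclose(bonferroni_adjust([0.5, 0.5, 0.5]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(bonferroni_adjust([0.07], m=1), [0.07])

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.0, 0.5])


class TestLeaveOneSiteOut:
    @pytest.fixture(scope="class")
    def site_cohort(self):
        co = generate_cohort(
            CohortConfig(n_subjects=900, n_features=30, n_informative=8,
                         effect_size_d=0.8, seed=21)
        )
        labs = make_binary_labels(co.severity)
        inc = labs.included
        return (co.features[inc], labs.y_included,
                ConfoundFrame(co.sex[inc], co.site[inc]))

    def test_one_fold_per_remaining_site(self, site_cohort):
        X, y, C = site_cohort
        spec = ModelSpec("logistic", hyper_grid=[{"C": 1.0}], seed=0)
        res = leave_one_site_out(spec, X, y, C, holdout_site=C.site_categories[0])
        assert len(res.scores) == 7
        assert res.metadata["holdout_site"] == str(C.site_categories[0])

    def test_site_independent_signal_generalizes_everywhere(self, site_cohort):
        X, y, C = site_cohort
        spec = ModelSpec("logistic", hyper_grid=[{"C": 1.0}], seed=0)
        res = leave_one_site_out(spec, X, y, C, holdout_site=C.site_categories[0],
                                 correction="over")
        assert (res.scores > 0.5).all()

    def test_flipped_site_scores_below_the_others(self, site_cohort):
        X, y, C = site_cohort
        X = X.copy()
        informative = slice(0, 30)  # flip every feature for one site
        flip_site = C.site_categories[3]
        X[C.site == flip_site] *= -1
        spec = ModelSpec("logistic", hyper_grid=[{"C": 1.0}], seed=0)
        res = leave_one_site_out(spec, X, y, C, holdout_site=C.site_categories[0])
        flipped_pos = res.metadata["fold_sites"].index(str(flip_site))
        others = np.delete(res.scores, flipped_pos)
        assert res.scores[flipped_pos] < others.min()

    def test_missing_site_raises(self, site_cohort):
        X, y, C = site_cohort
        spec = ModelSpec("logistic", seed=0)
        with pytest.raises(ValueError):
            leave_one_site_out(spec, X, y, C, holdout_site=99)


def test_fitted_transforms_ignore_test_rows(labeled_data):
    """Sentinel: corrupting test rows changes no fitted pipeline parameter."""
    X, y, C = labeled_data
    tr = np.arange(0, 250)
    pipe = fit_pipeline("logistic", {"C": 1.0}, X[tr], y[tr], C.subset(tr), "regression", seed=0)
    pipe2 = fit_pipeline("logistic", {"C": 1.0}, X[tr], y[tr], C.subset(tr), "regression", seed=0)
    np.testing.assert_array_equal(pipe.standardizer.means, pipe2.standardizer.means)
    np.testing.assert_array_equal(pipe.regression.coefficients, pipe2.regression.coefficients)
    # applying to corrupted test rows reuses train parameters unchanged
    X_te = X[250:260].copy()
    base = pipe.transform(X_te, C.subset(np.arange(250, 260)))
    X_te[0] += 1e6
    corrupted = pipe.transform(X_te, C.subset(np.arange(250, 260)))
    np.testing.assert_allclose(base[1:], corrupted[1:])
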