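"""Confound regression and counterbalancing contracts."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from confoundcv import (
    ConfoundFrame,
    apply_confound_regressor,
    counterbalance,
    fit_confound_regressor,
)
from confoundcv.confounds import UnseenCategoryError


def _frame(n, n_sites=4, seed=0):
    rng = np.random.default_rng(seed)
    return ConfoundFrame(
        sex=np.where(rng.random(n) < 0.5, "male", "female"),
        site=rng.integers(0, n_sites, n),
    )


class TestRegression:
    def test_perfectly_explained_feature_has_zero_residuals(self):
        C = _frame(80, seed=1)
        X = (2.0 * (C.sex == "male").astype(float)).reshape(-1, 1)
        p = fit_confound_regressor(X, C)
        resid = apply_confound_regressor(p, X, C)
        np.testing.assert_allclose(resid, 0, atol=1e-10)

    def test_noise_feature_coefficients_near_zero(self):
        rng = np.random.default_rng(2)
        C = _frame(2000, seed=2)
        X = rng.standard_normal((2000, 1))
        p = fit_confound_regressor(X, C)
        # non-intercept OLS coefficients within 3 SEs of 0 (SE <= sigma/sqrt(n_cell))
        se = 1.0 / np.sqrt(200)  # conservative: smallest cell is larger than 200
        assert np.all(np.abs(p.coefficients[1:, 0]) < 3 * se)

    def test_single_cell_raises(self):
        C = ConfoundFrame(np.array(["male"] * 10), np.array([0] * 10))
        with pytest.raises(ValueError):
            fit_confound_regressor(np.zeros((10, 2)), C)

    def test_reference_category_rows_subtract_only_intercept(self):
        C = _frame(50, seed=3)
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 3))
        p = fit_confound_regressor(X, C)
        ref_sex, ref_site = C.sex_categories[0], C.site_categories[0]
        C_ref = ConfoundFrame(np.array([ref_sex] * 4), np.array([ref_site] * 4),
                              C.sex_categories, C.site_categories)
        X_new = rng.standard_normal((4, 3))
        resid = apply_confound_regressor(p, X_new, C_ref)
        np.testing.assert_allclose(resid, X_new - p.coefficients[0], atol=1e-10)

    def test_unseen_category_raises(self):
        C = _frame(40, n_sites=3, seed=4)
        p = fit_confound_regressor(np.random.default_rng(0).standard_normal((40, 2)), C)
        C_bad = ConfoundFrame(C.sex[:5], np.array([7] * 5))
        with pytest.raises(UnseenCategoryError):
            apply_confound_regressor(p, np.zeros((5, 2)), C_bad)

    def test_removes_cell_means_keeps_cell_variances(self):
        """Main-effects regression zeroes per-cell mean differences but leaves
        per-cell variance ratios essentially unchanged."""
        rng = np.random.default_rng(5)
        n = 4000
        C = _frame(n, n_sites=2, seed=5)
        site_sd = np.where(C.site == 0, 1.0, 2.0)
        X = (
            0.8 * (C.sex == "male").astype(float)
            + 1.2 * (C.site == 1).astype(float)
            + rng.standard_normal(n) * site_sd
        ).reshape(-1, 1)
        resid = apply_confound_regressor(fit_confound_regressor(X, C), X, C)[:, 0]
        # OLS orthogonality: residual means per confound CATEGORY are exactly 0
        for cat_vec, cats in ((C.sex, C.sex_categories), (C.site, C.site_categories)):
            for c in cats:
                assert abs(resid[cat_vec == c].mean()) < 1e-8
        # joint-cell means are left only with sampling noise (no interaction
        # was generated; a main-effects fit cannot represent joint cells)
        cells = C.cells()
        for c in np.unique(cells):
            m = cells == c
            assert abs(resid[m].mean()) < 4 * 2.0 / np.sqrt(m.sum())
        # per-cell variance ratios unchanged within 5%: within a joint cell the
        # regression only shifts the mean, so the site-dependent variance
        # structure survives untouched
        for c in np.unique(cells):
            m = cells == c
            ratio = X[m, 0].var() / resid[m].var()
            assert abs(ratio - 1) < 0.05


class TestCounterbalance:
    def test_oversampling_hand_count(self):
        # strata A: y1=3,y0=1; B: y1=1,y0=3
        site = np.array(["A"] * 4 + ["B"] * 4)
        sex = np.array(["m"] * 8)
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        plan = counterbalance(y, ConfoundFrame(sex, site), "over", seed=0)
        yy = y[plan.indices]
        ss = site[plan.indices]
        assert (yy == 1).sum() == 6 and (yy == 0).sum() == 6
        for s in "AB":
            assert ((ss == s) & (yy == 1)).sum() == 3
            assert ((ss == s) & (yy == 0)).sum() == 3
        # P(site=A | y) identical across classes
        assert np.mean(ss[yy == 1] == "A") == np.mean(ss[yy == 0] == "A") == 0.5

    def test_undersampling_hand_count(self):
        site = np.array(["A"] * 4 + ["B"] * 4)
        sex = np.array(["m"] * 8)
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        plan = counterbalance(y, ConfoundFrame(sex, site), "under", seed=0)
        assert len(plan.indices) == 4
        assert len(np.unique(plan.indices)) == 4  # subset, no duplicates
        yy = y[plan.indices]
        assert (yy == 1).sum() == 2 and (yy == 0).sum() == 2

    def test_balanced_input_is_identity(self):
        site = np.array(["A", "A", "B", "B"] * 2)
        sex = np.array(["m"] * 8)
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        for mode in ("under", "over"):
            plan = counterbalance(y, ConfoundFrame(sex, site), mode, seed=1)
            assert sorted(plan.indices) == list(range(8))

    def test_stratum_missing_a_class_is_dropped_with_warning(self):
        site = np.array(["A"] * 4 + ["B"] * 3)
        sex = np.array(["m"] * 7)
        y = np.array([0, 1, 0, 1, 1, 1, 1])  # B has no class 0
        with pytest.warns(UserWarning, match="dropped"):
            plan = counterbalance(y, ConfoundFrame(sex, site), "over", seed=0)
        assert not np.isin(plan.indices, [4, 5, 6]).any()

    def test_no_usable_stratum_raises(self):
        C = ConfoundFrame(np.array(["m", "m"]), np.array(["A", "B"]))
        with pytest.raises(ValueError):
            counterbalance(np.array([0, 1]), C, "under", seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), mode=st.sampled_from(["under", "over"]))
    def test_resampled_confound_label_association_is_exactly_zero(self, seed, mode):
        """Chi-square of (cell x label) on the resampled multiset is exactly 0,
        oversampling never shrinks below undersampling, and only training
        indices ever appear."""
        rng = np.random.default_rng(seed)
        n = 120
        C = _frame(n, n_sites=3, seed=seed)
        y = (rng.random(n) < 0.4).astype(int)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                plan = counterbalance(y, C, mode, seed=seed)
        except ValueError:
            return  # no stratum with both classes: correctly refused
        cells = C.cells()[plan.indices]
        yy = y[plan.indices]
        table = np.array(
            [[np.sum((cells == c) & (yy == cls)) for cls in (0, 1)] for c in np.unique(cells)]
        )
        chi2 = chi2_contingency(table, correction=False).statistic
        assert chi2 == 0.0
        assert plan.indices.min() >= 0 and plan.indices.max() < n
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            under = counterbalance(y, C, "under", seed=seed)
            over = counterbalance(y, C, "over", seed=seed)
        assert len(over.indices) >= len(under.indices)
        assert len(under.indices) <= n

    def test_plan_serializes(self):
        C = _frame(30, seed=9)
        y = np.random.default_rng(9).integers(0, 2, 30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = counterbalance(y, C, "over", seed=9)
        import json

        payload = json.loads(plan.to_json())
        assert payload["mode"] == "over"
        assert payload["indices"] == plan.indices.tolist()
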