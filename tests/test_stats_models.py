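"""Statistics layer against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import neurofatigue as nf
from neurofatigue.errors import (
    CollinearityError,
    InvalidInputError,
    UnbalancedDesignError,
)


class TestBlockAverage:
    def _df(self, values_by_set, subjects=(1, 2)):
        rows = []
        for subj in subjects:
            for s, v in enumerate(values_by_set, 1):
                for rep in (1, 2):
                    rows.append({"subject": subj, "set": s, "rep": rep, "value": v})
        return pd.DataFrame(rows)

    def test_all_equal_is_100pct(self):
        out = nf.block_average(self._df([5.0] * 8))
        assert np.allclose(out["mean"], 100.0)

    def test_programmed_linear_decline_recovered(self):
        sched = np.linspace(1.0, 0.5, 20)
        out = nf.block_average(self._df(100 * sched))
        expected = [100 * sched[b * 4:(b + 1) * 4].mean() for b in range(5)]
        np.testing.assert_allclose(out["mean"], expected, rtol=1e-12)
        assert np.allclose(out["std"], 0.0)

    def test_single_subject_passthrough(self):
        out = nf.block_average(self._df([2.0, 1.0] * 4, subjects=(7,)),
                               grouping="five_intervals")
        assert len(out) == 5
        assert out["std"].isna().all() or np.allclose(out["std"].fillna(0), 0)

    def test_unknown_grouping(self):
        with pytest.raises(InvalidInputError):
            nf.block_average(self._df([1.0]), grouping="nope")


class TestPercentChange:
    def test_reference_case(self):
        assert nf.percent_change(100.0, 67.4) == pytest.approx(-32.6)
        assert nf.percent_change(7.0, 7.0) == 0.0

    def test_zero_pre_rejected(self):
        with pytest.raises(InvalidInputError):
            nf.percent_change(0.0, 5.0)

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        pre = np.array([320.0, 100.0])
        post = np.array([215.0, 70.0])
        mean, _ = nf.mean_percent_change(pre, post)
        ratio_of_means = (post.mean() - pre.mean()) / pre.mean() * 100
        assert mean == pytest.approx(((-105 / 320) + (-30 / 100)) / 2 * 100)
        assert mean != pytest.approx(ratio_of_means, abs=0.01)


class TestOLSStandardized:
    def _construct(self, betas, n=200, seed=0):
        r = np.random.default_rng(seed)
        z1, z2 = r.normal(size=n), r.normal(size=n)
        y = betas[0] * z1 + betas[1] * z2
        return y, pd.DataFrame({"z1": z1, "z2": z2})

    def test_constructed_betas_recovered(self):
        y, X = self._construct((0.64, 0.19))
        res = nf.ols_standardized(y, X)
        # standardized betas on z-scored data: b_j = beta_j * sd(x_j)/sd(y)
        sd_y = np.std(y, ddof=1)
        assert res.betas["z1"] == pytest.approx(0.64 * X["z1"].std() / sd_y, rel=1e-9)
        assert res.betas["z2"] == pytest.approx(0.19 * X["z2"].std() / sd_y, rel=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_identity_regression(self):
        r = np.random.default_rng(3)
        z = r.normal(size=50)
        res = nf.ols_standardized(z, pd.DataFrame({"z": z}))
        assert res.betas["z"] == pytest.approx(1.0, rel=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_r2_small(self):
        r = np.random.default_rng(5)
        res = nf.ols_standardized(r.normal(size=1000),
                                  pd.DataFrame({"x": r.normal(size=1000)}))
        assert res.r2 < 0.01

    def test_constant_column_rejected(self):
        with pytest.raises(CollinearityError):
            nf.ols_standardized(np.arange(10.0), pd.DataFrame({"c": np.ones(10)}))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(0.5, 20), b=st.floats(-100, 100))
    def test_betas_invariant_to_affine_predictor_rescaling(self, a, b):
        y, X = self._construct((0.4, 0.3), n=80, seed=7)
        base = nf.ols_standardized(y, X)
        X2 = X.copy()
        X2["z1"] = a * X2["z1"] + b
        res = nf.ols_standardized(y, X2)
        assert res.betas["z1"] == pytest.approx(base.betas["z1"], rel=1e-9)


class TestForwardStepwise:
    def test_noise_predictor_excluded(self):
        r = np.random.default_rng(11)
        z1, noise = r.normal(size=300), r.normal(size=300)
        y = z1 + 0.1 * r.normal(size=300)
        res = nf.forward_stepwise(y, pd.DataFrame({"signal": z1, "noise": noise}))
        assert res.included == ["signal"]

    def test_two_orthogonal_informative_included(self):
        r = np.random.default_rng(13)
        z1, z2 = r.normal(size=300), r.normal(size=300)
        y = 0.6 * z1 + 0.5 * z2 + 0.2 * r.normal(size=300)
        res = nf.forward_stepwise(y, pd.DataFrame({"z1": z1, "z2": z2}))
        assert set(res.included) == {"z1", "z2"}

    def test_all_noise_empty_model(self):
        r = np.random.default_rng(17)
        res = nf.forward_stepwise(r.normal(size=200),
                                  pd.DataFrame({"a": r.normal(size=200),
                                                "b": r.normal(size=200)}))
        assert res.included == [] and res.r2 == 0.0

    def test_collinear_twin_dropped(self):
        r = np.random.default_rng(19)
        z = r.normal(size=300)
        twin = z + 0.01 * r.normal(size=300)
        y = z + 0.2 * r.normal(size=300)
        res = nf.forward_stepwise(y, pd.DataFrame({"z": z, "twin": twin}))
        assert len(res.included) == 1

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_never_below_best_single_predictor(self, seed):
        r = np.random.default_rng(seed)
        X = pd.DataFrame({"a": r.normal(size=120), "b": r.normal(size=120)})
        y = 0.8 * X["a"].to_numpy() + 0.3 * r.normal(size=120)
        res = nf.forward_stepwise(y, X)
        best_single = max(nf.ols_standardized(y, X[[c]]).r2 for c in X.columns)
        assert res.r2 >= best_single - 1e-12


def brute_force_rm_anova(a):
    """Independent oracle: statsmodels AnovaRM on the long-format table."""
    from statsmodels.stats.anova import AnovaRM
    n, k = a.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "cond": np.tile(np.arange(k), n),
        "y": a.ravel()})
    res = AnovaRM(long, "y", "subject", within=["cond"]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


class TestRMAnova:
    def test_identical_columns_f_zero(self):
        a = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        f, _, _ = nf.rm_anova(a)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_textbook_table_hand_computation(self):
        # hand-computed sums of squares for a 3×3 table
        a = np.array([[3.0, 5.0, 7.0],
                      [4.0, 6.0, 9.0],
                      [5.0, 8.0, 10.0]])
        grand = a.mean()
        ss_cond = 3 * ((a.mean(0) - grand) ** 2).sum()
        ss_subj = 3 * ((a.mean(1) - grand) ** 2).sum()
        ss_err = ((a - grand) ** 2).sum() - ss_cond - ss_subj
        f_expected = (ss_cond / 2) / (ss_err / 4)
        f, df, _ = nf.rm_anova(a)
        assert df == (2, 4)
        assert f == pytest.approx(f_expected, rel=1e-12)

    def test_matches_statsmodels_on_random_tables(self):
        r = np.random.default_rng(23)
        for _ in range(10):
            a = r.normal(size=(5, 5))
            f, _, p = nf.rm_anova(a)
            f_ref, p_ref = brute_force_rm_anova(a)
            assert f == pytest.approx(f_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-8)

    def test_large_effect_tiny_p(self):
        r = np.random.default_rng(29)
        a = np.arange(4)[None, :] * 10.0 + r.normal(0, 0.1, size=(6, 4))
        _, _, p = nf.rm_anova(a)
        assert p < 1e-6

    def test_missing_cells_rejected(self):
        a = np.ones((3, 3))
        a[1, 1] = np.nan
        with pytest.raises(UnbalancedDesignError):
            nf.rm_anova(a)


class TestTukey:
    def test_equal_means_p_near_one(self):
        r = np.random.default_rng(31)
        a = r.normal(0, 1, size=(8, 3))
        a -= a.mean(axis=0, keepdims=True)  # force identical condition means
        out = nf.tukey_posthoc(a + 5.0)
        assert (out["p"] > 0.99).all()

    def test_separated_clusters_detected(self):
        r = np.random.default_rng(37)
        a = np.column_stack([r.normal(0, 0.1, 10), r.normal(0, 0.1, 10),
                             r.normal(10, 0.1, 10)])
        out = nf.tukey_posthoc(a)
        between = out[(out["a"] == 0) & (out["b"] == 2)]["p"].iloc[0]
        within = out[(out["a"] == 0) & (out["b"] == 1)]["p"].iloc[0]
        assert between < 0.001
        assert within > 0.05

    def test_two_conditions_orders_like_rm_anova(self):
        r = np.random.default_rng(41)
        a = np.column_stack([r.normal(0, 1, 12), r.normal(1.0, 1, 12)])
        _, _, p_anova = nf.rm_anova(a)
        p_tukey = nf.tukey_posthoc(a)["p"].iloc[0]
        # with k = 2 the studentized range test is the paired comparison
        assert p_tukey == pytest.approx(p_anova, rel=1e-6)


class TestMonoexpFit:
    def test_noise_free_recovery(self):
        t = np.arange(30, 601, 30.0)
        y = 4.5 + (23.7 - 4.5) * (1 - np.exp(-t / 60.0))
        fit = nf.fit_monoexp(t, y)
        assert fit.asymptote == pytest.approx(23.7, rel=1e-6)
        assert fit.tau == pytest.approx(60.0, rel=1e-4)

    def test_constant_series_flagged(self):
        fit = nf.fit_monoexp(np.arange(10.0), np.full(10, 8.0))
        assert fit.asymptote == 8.0
        assert not fit.tau_identifiable

    def test_noisy_recovery_within_3pct(self, rng):
        t = np.linspace(15, 600, 40)
        truth = 4.5 + (23.7 - 4.5) * (1 - np.exp(-t / 60.0))
        estimates = [nf.fit_monoexp(t, truth + rng.normal(0, 0.05 * 23.7, 40)).asymptote
                     for _ in range(30)]
        assert np.mean(estimates) == pytest.approx(23.7, rel=0.03)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            nf.fit_monoexp(np.arange(4.0), np.arange(4.0))


class TestLactate:
    def test_accumulation(self):
        assert nf.lactate_accumulation(1.3, 7.0) == pytest.approx(5.7)
        assert nf.lactate_accumulation(2.0, 2.0) == 0.0
        assert nf.lactate_accumulation(3.0, 2.0) == -1.0  # negative allowed
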