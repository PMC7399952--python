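import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from meddsurvey.errors import (
    ConfigurationError,
    LonelyPSUError,
    SeparationError,
    ValidationError,
)
from meddsurvey.survey import (
    SurveyDesign,
    SvyLogit,
    SvyOLS,
    four_year_weights,
    kernel_smooth,
    pairwise_contrasts_tukey,
    rao_scott_chisq,
    svy_mean,
    svy_proportion,
    svy_sd,
    svy_total,
)


class TestFourYearWeights:
    def test_two_cycle_pooling_halves(self):
        assert four_year_weights(1000.0) == 500.0

    def test_single_cycle_is_identity(self):
        assert four_year_weights(123.4, n_cycles=1) == 123.4

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValidationError):
            four_year_weights(0.0)


class TestDesign:
    def test_design_df_is_psus_minus_strata(self, clustered_design):
        d, _ = clustered_design
        assert d.df == 8 * 3 - 8

    def test_lonely_psu_errors_by_default(self):
        d = SurveyDesign([1, 1, 2], [1, 2, 1], [1.0, 1.0, 1.0])
        with pytest.raises(LonelyPSUError):
            svy_mean([1.0, 2.0, 3.0], d)

    def test_lonely_psu_centered_policy_runs(self):
        d = SurveyDesign([1, 1, 1, 2], [1, 2, 3, 1], np.ones(4), lonely_psu="centered")
        est = svy_mean([1.0, 2.0, 3.0, 4.0], d)
        assert est.se > 0

    def test_invalid_policy_rejected(self):
        with pytest.raises(ConfigurationError):
            SurveyDesign([1], [1], [1.0], lonely_psu="ignore")


class TestClassicalReductions:
    """Equal weights, one stratum, one record per PSU: i.i.d. estimators."""

    def test_mean_and_se(self, srs_design):
        rng = np.random.default_rng(0)
        x = rng.normal(size=150)
        est = svy_mean(x, srs_design(150))
        assert est.estimate == pytest.approx(x.mean(), abs=1e-12)
        assert est.se == pytest.approx(x.std(ddof=1) / np.sqrt(150), abs=1e-12)

    def test_sd_reduces_to_population_sd(self, srs_design):
        rng = np.random.default_rng(1)
        x = rng.normal(2, 3, 200)
        est = svy_sd(x, srs_design(200))
        assert est.estimate == pytest.approx(np.std(x, ddof=0), abs=1e-12)

    def test_ols_equals_textbook_ols(self, srs_design):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        y = 1.0 + 2.0 * x + rng.normal(size=100)
        X = pd.DataFrame({"const": 1.0, "x": x})
        res = SvyOLS(y, X, srs_design(100)).fit()
        ref = sm.OLS(y, X).fit()
        assert np.allclose(res.params, ref.params, atol=1e-10)

    def test_logit_matches_mle(self, srs_design):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        p = 1 / (1 + np.exp(-(0.4 + 0.9 * x)))
        y = (rng.random(300) < p).astype(float)
        X = pd.DataFrame({"const": 1.0, "x": x})
        res = SvyLogit(y, X, srs_design(300)).fit()
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(res.params, ref.params, atol=1e-8)

    def test_rao_scott_equals_pearson(self, srs_design):
        rng = np.random.default_rng(4)
        a, b = rng.integers(0, 3, 200), rng.integers(0, 2, 200)
        rs = rao_scott_chisq(a, b, srs_design(200))
        classical = stats.chi2_contingency(pd.crosstab(a, b), correction=False)
        assert rs.statistic == pytest.approx(classical[0], abs=1e-8)
        assert rs.p == pytest.approx(classical[1], abs=1e-8)

    def test_tukey_two_groups_equals_plain_t(self, srs_design):
        rng = np.random.default_rng(5)
        y = rng.normal(size=80)
        g = np.repeat(["a", "b"], 40)
        d = srs_design(80)
        tc = pairwise_contrasts_tukey(g, y, d)
        X = pd.DataFrame({"a": (g == "a").astype(float), "b": (g == "b").astype(float)})
        c = SvyOLS(y, X, d).fit().contrast([1.0, -1.0])
        assert tc["p_adjusted"].iloc[0] == pytest.approx(c.p, abs=1e-10)


class TestHandOracles:
    def test_two_stratum_horvitz_thompson_mean(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([2.0, 1.0, 3.0, 4.0])
        d = SurveyDesign([1, 1, 2, 2], [1, 2, 1, 2], w)
        assert svy_mean(vals, d).estimate == pytest.approx((w * vals).sum() / w.sum())
        assert svy_total(vals, d).estimate == pytest.approx((w * vals).sum())

    def test_logit_or_equals_weighted_cross_product(self):
        y = np.array([1, 1, 0, 0, 1, 0], dtype=float)
        x = np.array([1, 0, 1, 0, 1, 0], dtype=float)
        w = np.array([2.0, 1.5, 1.0, 3.0, 2.5, 1.0])
        d = SurveyDesign(np.ones(6), np.arange(6), w)
        res = SvyLogit(y, pd.DataFrame({"const": 1.0, "x": x}), d).fit()
        w11 = w[(y == 1) & (x == 1)].sum()
        w10 = w[(y == 1) & (x == 0)].sum()
        w01 = w[(y == 0) & (x == 1)].sum()
        w00 = w[(y == 0) & (x == 0)].sum()
        assert np.exp(res.params["x"]) == pytest.approx((w11 * w00) / (w10 * w01), rel=1e-8)

    def test_balanced_null_table_or_is_one(self):
        y = np.tile([1.0, 0.0], 40)
        x = np.repeat([1.0, 0.0], 40)
        d = SurveyDesign(np.ones(80), np.arange(80), np.ones(80))
        res = SvyLogit(y, pd.DataFrame({"const": 1.0, "x": x}), d).fit()
        assert np.exp(res.params["x"]) == pytest.approx(1.0, abs=1e-10)


class TestLinearizedSE:
    def test_se_matches_rao_wu_bootstrap(self):
        """Linearized SE vs the Rao-Wu stratified PSU bootstrap on a fixed cohort."""
        rng = np.random.default_rng(7)
        S, P, m = 8, 3, 40
        strata = np.repeat(np.arange(S), P * m)
        psu = np.tile(np.repeat(np.arange(P), m), S)
        u = rng.normal(0, 0.3, (S, P))
        x = rng.normal(1.0, 1.0, S * P * m) + u[strata, psu]
        w = np.exp(rng.normal(0, 0.4, S * P * m))
        est = svy_mean(x, SurveyDesign(strata, psu, w))
        B = 1000
        boots = np.empty(B)
        for b in range(B):
            xs, ws = [], []
            for s in range(S):
                for j in rng.integers(0, P, P - 1):
                    sel = (strata == s) & (psu == j)
                    xs.append(x[sel])
                    ws.append(w[sel] * P / (P - 1))
            xb, wb = np.concatenate(xs), np.concatenate(ws)
            boots[b] = np.sum(wb * xb) / np.sum(wb)
        assert est.se == pytest.approx(boots.std(ddof=1), rel=0.10)

    def test_exact_fit_has_zero_slope_se(self, srs_design):
        x = np.linspace(0, 1, 50)
        res = SvyOLS(2 * x, pd.DataFrame({"const": 1.0, "x": x}), srs_design(50)).fit()
        assert res.params["x"] == pytest.approx(2.0, abs=1e-12)
        assert res.bse["x"] == pytest.approx(0.0, abs=1e-10)


class TestWeightRescalingInvariance:
    def test_point_and_se_invariant(self, clustered_design):
        d, rng = clustered_design
        d2 = d.rescale(13.7)
        x = rng.normal(size=d.n)
        y = 1 + x + rng.normal(size=d.n)
        yb = (rng.random(d.n) < 0.4).astype(float)
        for f in (svy_mean, svy_sd):
            a, b = f(x, d), f(x, d2)
            assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
            assert a.se == pytest.approx(b.se, abs=1e-12)
        X = pd.DataFrame({"const": 1.0, "x": x})
        r1, r2 = SvyOLS(y, X, d).fit(), SvyOLS(y, X, d2).fit()
        assert np.allclose(r1.params, r2.params, atol=1e-12)
        assert np.allclose(r1.bse, r2.bse, atol=1e-12)
        l1, l2 = SvyLogit(yb, X, d).fit(), SvyLogit(yb, X, d2).fit()
        assert np.allclose(l1.params, l2.params, atol=1e-9)
        g = rng.integers(0, 3, d.n)
        c1, c2 = rao_scott_chisq(g, yb, d), rao_scott_chisq(g, yb, d2)
        assert c1.statistic == pytest.approx(c2.statistic, abs=1e-9)


class TestRegressionBehaviour:
    def test_rank_deficiency_names_columns(self, srs_design):
        x = np.arange(20.0)
        X = pd.DataFrame({"const": 1.0, "x": x, "x2": 2 * x})
        with pytest.raises(ValidationError, match="collinear"):
            SvyOLS(x, X, srs_design(20)).fit()

    def test_complete_separation_detected(self, srs_design):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = (x > 0).astype(float)
        X = pd.DataFrame({"const": 1.0, "x": x})
        with pytest.raises(SeparationError):
            SvyLogit(y, X, srs_design(40)).fit()

    def test_missing_rows_excluded_as_domain(self, clustered_design):
        d, rng = clustered_design
        x = rng.normal(size=d.n)
        y = 1 + 0.5 * x + rng.normal(size=d.n)
        y_missing = y.copy()
        y_missing[::5] = np.nan
        res = SvyOLS(y_missing, pd.DataFrame({"const": 1.0, "x": x}), d).fit()
        assert res.nobs == np.sum(~np.isnan(y_missing))

    def test_logit_and_ols_agree_in_sign_on_planted_effect(self, clustered_design):
        d, rng = clustered_design
        x = rng.normal(size=d.n)
        z = 0.4 * x + rng.normal(size=d.n)
        yb = (z > 0).astype(float)
        X = pd.DataFrame({"const": 1.0, "x": x})
        bo = SvyOLS(z, X, d).fit().params["x"]
        bl = SvyLogit(yb, X, d).fit().params["x"]
        assert np.sign(bo) == np.sign(bl) == 1.0

    def test_summary_and_odds_ratios(self, srs_design):
        rng = np.random.default_rng(9)
        x = rng.normal(size=120)
        y = (rng.random(120) < 1 / (1 + np.exp(-x))).astype(float)
        res = SvyLogit(y, pd.DataFrame({"const": 1.0, "x": x}), srs_design(120)).fit()
        ors = res.odds_ratios()
        ci = res.conf_int()
        assert np.allclose(ors["ci_low"], np.exp(ci["ci_low"]))
        assert "Survey-weighted logistic" in res.summary()

    def test_from_formula_with_categoricals(self, clustered_design):
        d, rng = clustered_design
        df = pd.DataFrame(
            {
                "y": rng.normal(size=d.n),
                "g": rng.choice(["a", "b", "c"], d.n),
                "x": rng.normal(size=d.n),
            }
        )
        res = SvyOLS.from_formula("y ~ x + C(g)", df, d).fit()
        assert {"Intercept", "x", "C(g)[T.b]", "C(g)[T.c]"} == set(res.params.index)


class TestTukeyContrasts:
    def test_identical_groups_all_p_near_one(self, srs_design):
        base = np.random.default_rng(8).normal(size=30)
        y = np.tile(base, 3)  # each group sees identical values
        g = np.repeat(["a", "b", "c"], 30)
        tc = pairwise_contrasts_tukey(g, y, srs_design(90))
        assert (tc["p_adjusted"] > 0.999).all()

    def test_singleton_group_rejected(self, srs_design):
        g = np.array(["a"] * 10 + ["b"])
        with pytest.raises(ValidationError, match="singleton"):
            pairwise_contrasts_tukey(g, np.arange(11.0), srs_design(11))


class TestRaoScott:
    def test_perfectly_independent_table_statistic_zero(self):
        a = np.repeat([0, 1], 50)
        b = np.tile([0, 1], 50)
        d = SurveyDesign(np.ones(100), np.arange(100), np.ones(100))
        assert rao_scott_chisq(a, b, d).pearson == pytest.approx(0.0, abs=1e-12)

    def test_single_level_variable_rejected(self, srs_design):
        with pytest.raises(ValidationError):
            rao_scott_chisq(np.zeros(20), np.arange(20) % 2, srs_design(20))


class TestKernelSmooth:
    def test_constant_response_fits_constant(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        grid, fit = kernel_smooth(x, np.full(200, 3.7), bandwidth=0.5)
        assert np.allclose(fit, 3.7, atol=1e-10)

    def test_huge_bandwidth_tends_to_weighted_mean(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        w = rng.uniform(0.5, 2.0, 200)
        _, fit = kernel_smooth(x, y, weights=w, bandwidth=1e6)
        assert np.allclose(fit, np.sum(w * y) / np.sum(w), atol=1e-6)

    def test_zero_mass_grid_point_missing(self):
        x = np.zeros(10)
        y = np.ones(10)
        _, fit = kernel_smooth(x, y, bandwidth=0.01, grid=np.array([0.0, 1e6]))
        assert fit[0] == pytest.approx(1.0)
        assert np.isnan(fit[1])

    def test_step_trend_recovered_monotone(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 10, 4000)
        y = (x > 5).astype(float) + rng.normal(0, 0.1, 4000)
        grid, fit = kernel_smooth(x, y, bandwidth=0.8, grid=np.linspace(1, 9, 20))
        assert (np.diff(fit) > -0.02).all()
        assert fit[0] < 0.2 and fit[-1] > 0.8
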