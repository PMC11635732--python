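"""Design-based estimators: reductions, hand fixtures and simulations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from foodsec import survey


def _stratified_design(rng, n, n_strata=10, sigma=0.5):
    stratum = rng.integers(0, n_strata, n)
    psu = rng.integers(0, 2, n)
    w = np.exp(rng.normal(0, sigma, n))
    return survey.SurveyDesign(stratum, psu, w)


class TestMultiyearWeights:
    def test_division_by_cycles(self):
        t = pd.DataFrame({"wtint2yr": [12_000.0], "wtmec2yr": [6_000.0]})
        out = survey.build_multiyear_weights(t, 6)
        assert out["wtint12yr"].iloc[0] == 2_000.0
        assert out["wtmec12yr"].iloc[0] == 1_000.0

    def test_single_cycle_is_identity(self):
        t = pd.DataFrame({"wtint2yr": [123.0, 456.0]})
        out = survey.build_multiyear_weights(t, 1)
        assert out["wtint12yr"].tolist() == [123.0, 456.0]

    def test_total_weight_scales_by_cycle_count(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"wtint2yr": rng.uniform(500, 5000, 100)})
        out = survey.build_multiyear_weights(t, 6)
        assert np.isclose(out["wtint12yr"].sum(), t["wtint2yr"].sum() / 6)

    def test_nonpositive_cycles_rejected(self):
        with pytest.raises(ValueError):
            survey.build_multiyear_weights(pd.DataFrame({"wtint2yr": [1.0]}), 0)


class TestSelectWeight:
    @pytest.mark.parametrize(
        "kind, column",
        [("interview", "wtint12yr"), ("mec", "wtmec12yr"), ("dietary", "wtdr2d12yr")],
    )
    def test_mapping(self, kind, column):
        assert survey.select_weight(kind) == column

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            survey.select_weight("examination")


class TestWeightedPrevalence:
    def test_equal_weights_single_stratum_equals_sample_fractions(self, srs_design):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 4, 500).astype(float)
        est = survey.weighted_prevalence(y, srs_design(500))
        frac = pd.Series(y).value_counts(normalize=True).sort_index()
        np.testing.assert_allclose(est["proportion"], frac.values, atol=1e-12)

    def test_hand_computed_weighted_shares(self):
        # 6 records, weights 1,1,2,2,3,3; categories 0,1,0,2,1,2
        # weighted totals: cat0 = 1+2 = 3; cat1 = 1+3 = 4; cat2 = 2+3 = 5
        design = survey.SurveyDesign(
            np.zeros(6, int), np.arange(6), np.array([1.0, 1, 2, 2, 3, 3])
        )
        y = np.array([0.0, 1, 0, 2, 1, 2])
        est = survey.weighted_prevalence(y, design)
        np.testing.assert_allclose(est["proportion"], [3 / 12, 4 / 12, 5 / 12])

    def test_invariant_to_uniform_weight_rescaling(self):
        rng = np.random.default_rng(2)
        n = 300
        design = _stratified_design(rng, n)
        y = rng.integers(0, 3, n).astype(float)
        a = survey.weighted_prevalence(y, design)
        scaled = survey.SurveyDesign(design.stratum, design.psu, design.weights * 7.3)
        b = survey.weighted_prevalence(y, scaled)
        np.testing.assert_allclose(a["proportion"], b["proportion"])
        np.testing.assert_allclose(a["se"], b["se"])

    def test_proportions_sum_to_one_and_ci_in_unit_interval(self):
        rng = np.random.default_rng(3)
        n = 400
        design = _stratified_design(rng, n)
        est = survey.weighted_prevalence(rng.integers(0, 4, n).astype(float), design)
        assert abs(est["proportion"].sum() - 1) < 1e-10
        assert (est["ci_low"] >= 0).all() and (est["ci_high"] <= 1).all()
        assert (est["ci_low"] <= est["proportion"]).all()
        assert (est["proportion"] <= est["ci_high"]).all()

    def test_lonely_psu_errors_unless_centered(self):
        design = survey.SurveyDesign(
            np.array([0, 0, 1]), np.array([0, 1, 0]), np.ones(3)
        )
        with pytest.raises(ValueError, match="single PSU"):
            survey.weighted_prevalence(np.array([0.0, 1, 0]), design)
        centered = survey.SurveyDesign(
            design.stratum, design.psu, design.weights, lonely_psu="center"
        )
        est = survey.weighted_prevalence(np.array([0.0, 1, 0]), centered)
        assert np.isfinite(est["se"]).all()


class TestRaoScott:
    def test_srs_statistic_matches_textbook_pearson(self, srs_design):
        rng = np.random.default_rng(4)
        n = 600
        a = rng.integers(0, 2, n)
        b = (a + rng.integers(0, 3, n)) % 3
        res = survey.rao_scott_test(a, b, srs_design(n))
        chi2 = scipy.stats.chi2_contingency(pd.crosstab(a, b), correction=False)[0]
        assert np.isclose(res["X2"], chi2, rtol=1e-10)
        # under SRS the design-effect eigenvalues are ~1, so F ~ X2/d
        assert np.isclose(res["statistic"], chi2 / 2, rtol=0.1)

    def test_perfect_association_p_near_zero(self, srs_design):
        a = np.repeat([0, 1], 100)
        res = survey.rao_scott_test(a, a, srs_design(200))
        assert res["p"] < 1e-10

    def test_degenerate_margin_rejected(self, srs_design):
        with pytest.raises(ValueError):
            survey.rao_scott_test(np.zeros(50), np.arange(50) % 2, srs_design(50))

    def test_type_one_error_near_nominal_under_independence(self):
        rng = np.random.default_rng(5)
        reps, n, alpha = 500, 600, 0.05
        rejections = 0
        for _ in range(reps):
            design = _stratified_design(rng, n, sigma=0.4)
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 3, n)
            res = survey.rao_scott_test(a, b, design)
            rejections += res["p"] < alpha
        assert 0.03 <= rejections / reps <= 0.07


class TestDesignTTest:
    def test_identical_groups_adjusted_p_is_one(self, srs_design):
        y = np.tile([1.0, 2.0, 3.0], 40)
        g = np.repeat([0, 1], 60)
        out = survey.design_ttest_bonferroni(y, g, srs_design(120))
        assert out["p_adjusted"].iloc[0] == 1.0
        assert abs(out["difference"].iloc[0]) < 1e-12

    def test_four_groups_give_six_pairs(self, srs_design):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 4, 200)
        y = rng.normal(size=200)
        out = survey.design_ttest_bonferroni(y, g, srs_design(200))
        assert len(out) == 6
        assert (out["p_adjusted"] <= 1).all()

    def test_planted_two_sd_shift_detected_in_all_pairs(self):
        rng = np.random.default_rng(7)
        n_group = 500
        g = np.repeat([0, 1, 2, 3], n_group)
        y = rng.normal(loc=2.0 * g, scale=1.0, size=4 * n_group)
        design = _stratified_design(rng, 4 * n_group)
        out = survey.design_ttest_bonferroni(y, g, design)
        assert (out["p_adjusted"] < 0.01).all()

    def test_unknown_group_label_rejected(self, srs_design):
        with pytest.raises(ValueError, match="unknown group"):
            survey.design_ttest_bonferroni(
                np.ones(10), np.zeros(10), srs_design(10), group_pairs=[(0, 9)]
            )


@pytest.fixture(scope="module")
def regression_fixture():
    rng = np.random.default_rng(8)
    n = 500
    g = rng.integers(0, 4, n)
    x = rng.normal(size=n)
    eta = -1.5 + 0.6 * g + 0.5 * x
    y_bin = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    y_lin = eta + rng.normal(size=n)
    return pd.DataFrame({"g": g.astype(float), "x": x, "y_bin": y_bin, "y_lin": y_lin})


class TestWeightedLogistic:
    def test_srs_reduces_to_ordinary_logistic(self, regression_fixture, srs_design):
        tab = regression_fixture
        design = srs_design(len(tab))
        res = survey.weighted_logistic(
            tab, "y_bin", {"column": "g", "reference": 0.0}, ["x"], design
        )
        X = np.column_stack(
            [np.ones(len(tab))]
            + [(tab["g"] == k).astype(float) for k in (1.0, 2.0, 3.0)]
            + [tab["x"]]
        )
        oracle = sm.GLM(tab["y_bin"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(res["estimate"], oracle.params, atol=1e-8)

    def test_odds_ratio_is_exp_estimate(self, regression_fixture, srs_design):
        tab = regression_fixture
        res = survey.weighted_logistic(
            tab, "y_bin", {"column": "g", "reference": 0.0}, ["x"], srs_design(len(tab))
        )
        np.testing.assert_allclose(res["odds_ratio"], np.exp(res["estimate"]))

    def test_constant_outcome_is_error(self, regression_fixture, srs_design):
        tab = regression_fixture.copy()
        tab["y_bin"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            survey.weighted_logistic(
                tab, "y_bin", {"column": "g", "reference": 0.0}, [], srs_design(len(tab))
            )

    def test_empty_exposure_level_is_error(self, regression_fixture, srs_design):
        tab = regression_fixture
        with pytest.raises(ValueError, match="empty"):
            survey.weighted_logistic(
                tab,
                "y_bin",
                {"column": "g", "reference": 0.0, "levels": [0.0, 1.0, 9.0]},
                [],
                srs_design(len(tab)),
            )

    def test_separation_is_error(self, srs_design):
        n = 80
        tab = pd.DataFrame(
            {"g": np.repeat([0.0, 1.0], n // 2), "y": np.repeat([0.0, 1.0], n // 2)}
        )
        with pytest.raises(ValueError):
            survey.weighted_logistic(
                tab, "y", {"column": "g", "reference": 0.0}, [], srs_design(n)
            )


class TestWeightedLinear:
    def test_srs_reduces_to_ols(self, regression_fixture, srs_design):
        tab = regression_fixture
        res = survey.weighted_linear(
            tab, "y_lin", {"column": "g", "reference": 0.0}, ["x"], srs_design(len(tab))
        )
        X = np.column_stack(
            [np.ones(len(tab))]
            + [(tab["g"] == k).astype(float) for k in (1.0, 2.0, 3.0)]
            + [tab["x"]]
        )
        oracle = sm.OLS(tab["y_lin"], X).fit()
        np.testing.assert_allclose(res["estimate"], oracle.params, atol=1e-8)

    def test_covariate_free_intercept_is_weighted_mean(self):
        rng = np.random.default_rng(9)
        n = 200
        w = rng.uniform(0.5, 3.0, n)
        y = rng.normal(5, 2, n)
        tab = pd.DataFrame({"y": y, "g": np.zeros(n)})
        design = survey.SurveyDesign(np.zeros(n, int), np.arange(n), w)
        res = survey.weighted_linear(
            tab, "y", {"column": "g", "reference": 0.0}, [], design
        )
        assert np.isclose(
            res.loc[res["term"] == "intercept", "estimate"].iloc[0],
            np.average(y, weights=w),
            atol=1e-10,
        )


class TestCompareModels:
    def _specs(self):
        exposure = {"column": "g", "reference": 0.0}
        a = {"outcome": "y1", "exposure": exposure, "covariates": ["x"], "kind": "linear"}
        b = {"outcome": "y2", "exposure": exposure, "covariates": ["x"], "kind": "linear"}
        return a, b

    def test_model_compared_with_itself_has_zero_difference(self):
        rng = np.random.default_rng(10)
        n = 400
        tab = pd.DataFrame(
            {
                "g": rng.integers(0, 4, n).astype(float),
                "x": rng.normal(size=n),
            }
        )
        tab["y1"] = 2.0 + 0.5 * tab["g"] + rng.normal(size=n)
        tab["y2"] = tab["y1"]
        design = _stratified_design(rng, n)
        spec_a, spec_b = self._specs()
        out = survey.compare_models(tab, spec_a, spec_b, design, reps=50, seed=0)
        np.testing.assert_allclose(out["difference"], 0.0, atol=1e-12)
        assert (out["p"] > 0.9).all()

    def test_planted_coefficient_gap_detected(self):
        rng = np.random.default_rng(11)
        n = 3000
        tab = pd.DataFrame(
            {
                "g": rng.integers(0, 4, n).astype(float),
                "x": rng.normal(size=n),
            }
        )
        tab["y1"] = 1.0 + 0.5 * tab["g"] + 0.3 * tab["x"] + rng.normal(size=n)
        tab["y2"] = tab["y1"] - 1.0 * (tab["g"] > 0)  # gap of 1.0 on every term
        design = _stratified_design(rng, n)
        spec_a, spec_b = self._specs()
        out = survey.compare_models(tab, spec_a, spec_b, design, reps=200, seed=1)
        assert (out["p"] < 0.05).all()
        assert (out["ci_low"] > 0).all()
        np.testing.assert_allclose(out["difference"], 1.0, atol=0.2)
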