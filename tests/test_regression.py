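"""Design construction, likelihoods, ML fitting, and Wald inference."""

import numpy as np
import pandas as pd
import pytest

from countdisp.distributions import poisson_logpmf, sample_gp_counts
from countdisp.regression import (
    fit_model,
    negloglik,
    predict_mean,
    wald_inference,
)
from countdisp.synthetic import SyntheticConfig, generate

from conftest import records_to_design


class TestBuildDesign:
    def test_full_specification_has_13_columns(self, council_records):
        records, _ = council_records
        design = records_to_design(records)
        assert design.k == 13
        assert design.column_names[0] == "(Intercept)"
        assert np.all(design.values[:, 0] == 1.0)

    def test_reference_levels_encode_to_zero_dummies(self):
        df = pd.DataFrame(
            {
                "council_id": ["A"],
                "zone": ["Northern"],
                "residence": ["Rural"],
                "pplhiv_pct": [5.0],
                "population": [1e5],
                "gdp": [1e8],
                "n_facilities": [20],
                "pct_male": [45.0],
                "count_5_59": [10],
                "count_60plus": [5],
            }
        )
        design = records_to_design(df)
        # intercept + 5 continuous, then 7 dummies all zero
        assert np.all(design.values[0, 6:] == 0.0)

    def test_complete_case_drops_and_reports_missing(self, council_records):
        records, truth = council_records
        design = records_to_design(records)
        n_missing = int(records["count_5_59"].isna().sum())
        assert design.n_used == len(records) - n_missing
        assert len(design.dropped_rows) == n_missing

    def test_unknown_level_raises(self, council_records):
        records, _ = council_records
        bad = records.copy()
        bad.loc[0, "zone"] = "Coastal"
        with pytest.raises(ValueError, match="Coastal"):
            records_to_design(bad)

    def test_log_transform_requires_positive_values(self, council_records):
        records, _ = council_records
        bad = records.copy()
        bad.loc[0, "population"] = 0.0
        with pytest.raises(ValueError, match="population"):
            records_to_design(bad)


class TestNegLogLik:
    def test_intercept_only_poisson_matches_pointwise_pmf(self):
        X = np.ones((3, 1))
        y = np.array([2.0, 2.0, 2.0])
        got = negloglik("poisson", [np.log(2.0)], None, X, y)
        expected = -3.0 * poisson_logpmf(2, 2.0)  # = 3.920559
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(3.920559, abs=1e-6)

    def test_gp_at_theta_one_equals_poisson(self, small_design):
        X, y = small_design
        beta = np.array([0.8, 0.2, -0.1])
        assert negloglik("gp", beta, 1.0, X, y) == pytest.approx(
            negloglik("poisson", beta, None, X, y), abs=1e-10
        )

    def test_nb_at_huge_alpha_approaches_poisson(self, small_design):
        X, y = small_design
        beta = np.array([0.8, 0.2, -0.1])
        assert negloglik("nb", beta, 1e8, X, y) == pytest.approx(
            negloglik("poisson", beta, None, X, y), abs=1e-4
        )

    def test_overflow_guard(self, small_design):
        X, y = small_design
        assert negloglik("poisson", [1e3, 0, 0], None, X, y) == np.inf

    def test_infeasible_gp_theta_rejected(self, small_design):
        X, y = small_design
        assert negloglik("gp", [0.8, 0.2, -0.1], 0.3, X, y) == np.inf


class TestFitModel:
    def test_intercept_only_poisson_closed_form(self, rng):
        y = rng.poisson(5.0, size=200)
        fit = fit_model("poisson", np.ones((200, 1)), y)
        assert fit.coefficients[0] == pytest.approx(np.log(y.mean()), abs=1e-8)
        assert fit.converged

    def test_poisson_score_identity(self, council_records):
        records, _ = council_records
        design = records_to_design(records)
        fit = fit_model("poisson", design)
        mu = predict_mean(fit, design)
        assert abs(np.sum(design.response - mu)) < 1e-6 * design.n_used

    def test_gp_recovers_known_parameters_at_n2000(self):
        rng = np.random.default_rng(77)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta_true = np.array([1.0, 0.5])
        y = sample_gp_counts(np.exp(X @ beta_true), 2.0, rng)
        fit = fit_model("gp", X, y)
        assert fit.converged
        for est, se, truth in zip(
            fit.coefficients, fit.std_errors, [*beta_true, np.log(2.0)]
        ):
            assert abs(est - truth) < 3 * se

    def test_gp_on_poisson_data_finds_theta_near_one(self):
        rng = np.random.default_rng(5)
        n = 5000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(X @ np.array([1.2, 0.3])))
        fit = fit_model("gp", X, y)
        assert 0.9 <= fit.dispersion <= 1.1

    def test_gp_loglik_nests_poisson(self, council_records):
        records, _ = council_records
        design = records_to_design(records)
        ll_pois = fit_model("poisson", design).loglik
        assert fit_model("gp", design).loglik >= ll_pois - 1e-6
        assert fit_model("nb", design).loglik >= ll_pois - 1e-6

    def test_poisson_matches_statsmodels_glm(self, council_records):
        import statsmodels.api as sm

        records, _ = council_records
        design = records_to_design(records)
        fit = fit_model("poisson", design)
        ref = sm.GLM(design.response, design.values, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.std_errors, ref.bse, rtol=1e-4)

    def test_rank_deficient_design_raises(self, rng):
        X = np.column_stack([np.ones(50), np.ones(50)])
        y = rng.poisson(3.0, size=50)
        with pytest.raises(np.linalg.LinAlgError):
            fit_model("poisson", X, y)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            fit_model("poisson", np.ones((1, 1)), np.array([2.0]))


class TestWaldInference:
    @pytest.mark.parametrize(
        "estimate,se,z",
        [(0.0616, 0.0241, 2.556), (-0.1507, 0.0306, -4.925), (0.0, 1.0, 0.0)],
    )
    def test_z_ratio_arithmetic(self, estimate, se, z):
        from scipy.stats import norm

        got_z = estimate / se
        assert got_z == pytest.approx(z, abs=0.005)
        p = 2 * norm.sf(abs(got_z))
        if estimate == 0.0:
            assert p == pytest.approx(1.0)

    def test_table_columns_and_consistency(self, council_records):
        records, _ = council_records
        fit = fit_model("gp", records_to_design(records))
        table = wald_inference(fit)
        assert list(table.columns) == ["estimate", "std_error", "z_value", "p_value"]
        np.testing.assert_allclose(
            table["z_value"], table["estimate"] / table["std_error"]
        )
        assert ((table["p_value"] >= 0) & (table["p_value"] <= 1)).all()


class TestPredictMean:
    def test_urban_dummy_multiplies_mean_by_exp_coefficient(self, council_records):
        records, _ = council_records
        design = records_to_design(records)
        fit = fit_model("gp", design)
        x0 = np.zeros(13)
        x0[0] = 1.0
        x1 = x0.copy()
        x1[design.column_names.index("Urban")] = 1.0
        mu0, mu1 = predict_mean(fit, np.vstack([x0, x1]))
        urban_coef = fit.beta[design.column_names.index("Urban")]
        assert mu1 / mu0 == pytest.approx(np.exp(urban_coef), rel=1e-10)

    def test_published_prediction_equation_at_reference(self):
        # prediction at all-zero covariates of the published GP equation
        assert np.exp(3.540) == pytest.approx(34.47, abs=0.01)

    def test_training_mean_matches_ybar_for_poisson(self, council_records):
        records, _ = council_records
        design = records_to_design(records)
        fit = fit_model("poisson", design)
        assert predict_mean(fit, design).mean() == pytest.approx(
            design.response.mean(), rel=1e-6
        )

    def test_column_mismatch_raises(self, council_records):
        records, _ = council_records
        fit = fit_model("poisson", records_to_design(records))
        with pytest.raises(ValueError):
            predict_mean(fit, np.ones((4, 5)))


def test_poisson_ses_anticonservative_under_overdispersion():
    """On GP data with theta=2, Poisson SEs understate uncertainty."""
    smaller = 0
    total = 0
    for rep in range(20):
        records, _ = generate(SyntheticConfig(seed=900 + rep, missing_rate=0.0))
        design = records_to_design(records)
        pois = fit_model("poisson", design)
        gp = fit_model("gp", design)
        smaller += int(np.sum(pois.std_errors < gp.std_errors[:13]))
        total += 13
    assert smaller / total >= 0.9
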