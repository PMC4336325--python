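"""Survey preparation rules and the Poisson log-normal GLMM."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import farmbird as fb
from farmbird.abundance import (
    fit_glmm,
    overdispersion_ratio,
    predict_abundance,
    predictive_power,
    prepare_counts,
    r2_mixed,
)
from conftest import make_recovery_dataset


class TestPrepareCounts:
    def test_max_of_two_visits_for_residents(self, tiny_visits, tiny_species_frame):
        out = prepare_counts(tiny_visits, tiny_species_frame)
        res = out[(out.species_id == "resident")].iloc[0]
        assert res["abundance"] == 5  # max(3, 5)

    def test_second_visit_only_for_migrants(self, tiny_visits, tiny_species_frame):
        out = prepare_counts(tiny_visits, tiny_species_frame)
        mig = out[(out.species_id == "migrant")].iloc[0]
        assert mig["abundance"] == 2  # visit2 despite visit1 = 7

    def test_low_farmland_square_excluded(self, tiny_visits, tiny_species_frame):
        # sq1 has 4/10 farmland points and large counts on every point; none
        # of them may leak into the regional abundance or the effort
        out = prepare_counts(tiny_visits, tiny_species_frame)
        assert (out["n_points"] == 5).all()
        assert out["abundance"].max() <= 5

    def test_unknown_species_is_reference_error(self, tiny_visits, tiny_species_frame):
        bad = tiny_visits.copy()
        bad.loc[0, "species_id"] = "ghost"
        with pytest.raises(KeyError, match="ghost"):
            prepare_counts(bad, tiny_species_frame)

    def test_zero_rows_kept_for_undetected_species(self, tiny_visits, tiny_species_frame):
        # both species get a row for region A x 2001 even if all counts were 0
        zeroed = tiny_visits.copy()
        zeroed.loc[zeroed.species_id == "migrant", ["visit1_count", "visit2_count"]] = 0
        out = prepare_counts(zeroed, tiny_species_frame)
        mig = out[out.species_id == "migrant"]
        assert len(mig) == 1 and mig.iloc[0]["abundance"] == 0

    def test_roundtrip_from_generator(self, small_regions, small_species):
        surveys = fb.generate_surveys(small_regions, small_species, [2001, 2002], seed=6)
        out = prepare_counts(surveys, small_species)
        assert set(out.columns) == {"species_id", "region_id", "year", "abundance", "n_points"}
        assert (out["abundance"] >= 0).all()
        assert (out["n_points"] >= 1).all()
        # effort matches what the generator recorded on the regions
        for r in small_regions:
            rows = out[(out.region_id == r.region_id) & (out.year == 2001)]
            if len(rows):
                assert (rows["n_points"] == r.n_points[2001]).all()


class TestFitGLMM:
    def test_intercept_only_constant_counts(self):
        df = pd.DataFrame({"abundance": [7] * 30, "region_id": ["r"] * 30, "year": [1] * 30})
        fit = fit_glmm(df, covariates=[], random_effects=())
        assert fit.params["alpha"] == pytest.approx(np.log(7), abs=1e-6)

    def test_matches_plain_glm_oracle_without_random_effects(self):
        df = make_recovery_dataset(101, n_regions=150, n_years=3,
                                   sd_region=0.0, sd_year=0.0, sd_obs=0.0)
        covs = ["suitability", "farmland_prop"]
        fit = fit_glmm(df, covs, random_effects=())
        X = sm.add_constant(df[covs].to_numpy())
        oracle = sm.GLM(df["abundance"], X, family=sm.families.Poisson()).fit()
        assert fit.params["alpha"] == pytest.approx(oracle.params.iloc[0], abs=1e-3)
        assert fit.params["suitability"] == pytest.approx(oracle.params.iloc[1], abs=1e-3)
        assert fit.params["farmland_prop"] == pytest.approx(oracle.params.iloc[2], abs=1e-3)
        assert fit.se["suitability"] == pytest.approx(oracle.bse.iloc[1], rel=1e-2)

    def test_all_zero_response_rejected(self):
        df = pd.DataFrame({"abundance": [0] * 10, "region_id": list("ab") * 5,
                           "year": [1, 2] * 5})
        with pytest.raises(ValueError, match="zero"):
            fit_glmm(df, covariates=[])

    def test_variance_components_recovered(self):
        df = make_recovery_dataset(55)
        fit = fit_glmm(df, ["suitability", "farmland_prop"])
        assert fit.converged
        assert np.sqrt(fit.var_region) == pytest.approx(0.3, abs=0.12)
        assert np.sqrt(fit.var_obs) == pytest.approx(0.2, abs=0.12)

    def test_unknown_random_effect_rejected(self):
        df = make_recovery_dataset(1, n_regions=10, n_years=2)
        with pytest.raises(ValueError, match="random"):
            fit_glmm(df, [], random_effects=("plot",))


class TestOverdispersion:
    def test_equidispersed_ratio_near_one(self):
        ratios = [
            overdispersion_ratio(
                fit_glmm(
                    make_recovery_dataset(200 + i, n_regions=60, n_years=3,
                                          sd_region=0.2, sd_year=0.0, sd_obs=0.0),
                    ["suitability", "farmland_prop"],
                    random_effects=("region", "year"),
                )
            )
            for i in range(8)
        ]
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_overdispersed_data_flagged_without_olre(self):
        df = make_recovery_dataset(300, n_regions=60, n_years=3,
                                   sd_region=0.2, sd_year=0.0, sd_obs=1.0)
        fit = fit_glmm(df, ["suitability", "farmland_prop"], random_effects=("region", "year"))
        ratio_no_olre = overdispersion_ratio(fit)
        assert ratio_no_olre > 1.5
        fit_olre = fit_glmm(df, ["suitability", "farmland_prop"])
        ratio_olre = overdispersion_ratio(fit_olre)
        assert abs(ratio_olre - 1.0) < abs(ratio_no_olre - 1.0)


class TestR2Mixed:
    def test_formula_on_extracted_components(self):
        df = make_recovery_dataset(77, n_regions=80, n_years=3)
        fit = fit_glmm(df, ["suitability", "farmland_prop"])
        r2m, r2c = r2_mixed(fit)
        var_f = float(np.var(fit._eta_fixed))
        var_r = fit.total_random_variance()
        lam = float(np.mean(np.exp(fit._eta_fixed + 0.5 * var_r)))
        var_d = float(np.log1p(1.0 / lam))
        assert r2m == pytest.approx(var_f / (var_f + var_r + var_d), abs=1e-10)
        assert r2c == pytest.approx((var_f + var_r) / (var_f + var_r + var_d), abs=1e-10)
        assert 0 < r2m <= r2c < 1

    def test_null_fixed_effects_give_near_zero_marginal(self):
        df = make_recovery_dataset(88, n_regions=80, n_years=3)
        rng = np.random.default_rng(0)
        df["noise"] = rng.normal(size=len(df))  # unrelated covariate
        fit = fit_glmm(df, ["noise"])
        r2m, _ = r2_mixed(fit)
        assert r2m < 0.05


class TestPrediction:
    def test_exponential_back_transform(self):
        df = pd.DataFrame({"abundance": [3] * 20, "region_id": list("ab") * 10,
                           "year": [1, 2] * 10})
        fit = fit_glmm(df, covariates=[], random_effects=())
        fit.params["alpha"] = 1.0
        out = predict_abundance(fit, pd.DataFrame(index=range(3)))
        np.testing.assert_allclose(out, np.e)

    def test_hand_computed_linear_predictor(self):
        df = make_recovery_dataset(5, n_regions=30, n_years=3)
        fit = fit_glmm(df, ["suitability", "farmland_prop"], random_effects=())
        new = pd.DataFrame({"suitability": [0.3], "farmland_prop": [0.6]})
        expect = np.exp(
            fit.params["alpha"] + 0.3 * fit.params["suitability"] + 0.6 * fit.params["farmland_prop"]
        )
        assert predict_abundance(fit, new)[0] == pytest.approx(expect, rel=1e-10)

    def test_future_equals_current_gives_equal_predictions(self):
        df = make_recovery_dataset(6, n_regions=30, n_years=3)
        fit = fit_glmm(df, ["suitability", "farmland_prop"])
        cov = df[["region_id", "suitability", "farmland_prop"]].drop_duplicates("region_id")
        np.testing.assert_array_equal(predict_abundance(fit, cov), predict_abundance(fit, cov))

    def test_missing_covariate_named(self):
        df = make_recovery_dataset(7, n_regions=30, n_years=3)
        fit = fit_glmm(df, ["suitability", "farmland_prop"], random_effects=())
        with pytest.raises(ValueError, match="farmland_prop"):
            predict_abundance(fit, pd.DataFrame({"suitability": [0.5]}))

    def test_training_mean_roundtrip_within_two_percent(self):
        df = make_recovery_dataset(8)
        fit = fit_glmm(df, ["suitability", "farmland_prop"])
        assert fit.fitted.mean() == pytest.approx(df["abundance"].mean(), rel=0.02)

    def test_unseen_region_uses_population_level(self):
        df = make_recovery_dataset(9, n_regions=30, n_years=3)
        fit = fit_glmm(df, ["suitability", "farmland_prop"])
        new = pd.DataFrame({"suitability": [0.5], "farmland_prop": [0.5],
                            "region_id": ["nowhere"], "year": [2099]})
        pop = predict_abundance(fit, new.drop(columns=["region_id", "year"]))
        assert predict_abundance(fit, new)[0] == pytest.approx(pop[0])


class TestPredictivePower:
    def test_informative_model_scores_high(self):
        df = make_recovery_dataset(21, n_regions=120, n_years=4, sd_obs=0.1)
        r2 = predictive_power(df, ["suitability", "farmland_prop"], seed=2)
        assert 0.2 < r2 <= 1.0

    def test_seed_determinism(self):
        df = make_recovery_dataset(22, n_regions=60, n_years=3)
        a = predictive_power(df, ["suitability"], seed=5)
        b = predictive_power(df, ["suitability"], seed=5)
        assert a == b

    def test_too_few_rows_rejected(self):
        df = make_recovery_dataset(23, n_regions=2, n_years=2).head(3)
        with pytest.raises(ValueError):
            predictive_power(df, ["suitability"], seed=1)
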