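"""Change statistics, specialization index and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

import farmbird as fb
from farmbird.forecast import (
    DEFAULT_COMBOS,
    DriverCombination,
    classify_main_habitat,
    cochran_sem,
    compute_ssig,
    driver_decomposition,
    one_sample_t,
    region_weight,
    symmetric_change,
    tukey_hsd,
    weighted_mean_sd,
)
from conftest import make_recovery_dataset
from farmbird.abundance import fit_glmm


class TestSymmetricChange:
    @pytest.mark.parametrize(
        "cur,fut,expected", [(1.0, 1.0, 0.0), (1.0, 3.0, 1.0), (2.0, 0.0, -2.0), (0.0, 0.0, 0.0)]
    )
    def test_reference_values(self, cur, fut, expected):
        assert symmetric_change(cur, fut) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            symmetric_change(-1.0, 2.0)

    @given(
        cur=st.floats(0, 1e6, allow_subnormal=False),
        fut=st.floats(0, 1e6, allow_subnormal=False),
    )
    def test_bounded_and_antisymmetric(self, cur, fut):
        c = symmetric_change(cur, fut)
        assert -2.0 <= c <= 2.0
        assert symmetric_change(fut, cur) == pytest.approx(-c, abs=1e-12)
        if cur + fut > 0:
            assert np.sign(c) == np.sign(fut - cur)


class TestRegionWeight:
    @pytest.mark.parametrize("area,n,expected", [(100, 10, 10.0), (50, 1, 50.0)])
    def test_ratio(self, area, n, expected):
        assert region_weight(area, n) == pytest.approx(expected)

    def test_rescaling_areas_leaves_weighted_mean(self):
        rng = np.random.default_rng(0)
        areas, npts = rng.uniform(11, 4413, 30), rng.integers(1, 30, 30)
        values = rng.normal(size=30)
        w1 = region_weight(areas, npts)
        w2 = region_weight(3.7 * areas, npts)
        m1, _ = weighted_mean_sd(values, w1)
        m2, _ = weighted_mean_sd(values, w2)
        assert m1 == pytest.approx(m2)

    def test_zero_points_rejected(self):
        with pytest.raises(ValueError):
            region_weight(10.0, 0)


class TestWeightedMeanSD:
    def test_equal_weights_mean(self):
        mean, _ = weighted_mean_sd([0.1, 0.3])
        assert mean == pytest.approx(0.2)

    def test_weighted_mean(self):
        mean, _ = weighted_mean_sd([0.0, 1.0], [1.0, 3.0])
        assert mean == pytest.approx(0.75)

    def test_equal_weights_reduce_to_sample_sd(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        _, sd = weighted_mean_sd(x, np.full(50, 2.5))
        assert sd == pytest.approx(x.std(ddof=1))
        assert cochran_sem(x, np.full(50, 2.5)) == pytest.approx(x.std(ddof=1) / np.sqrt(50))

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(3, 40)
            x = rng.normal(size=n)
            w = rng.uniform(0.1, 5.0, size=n)
            mean, sd = weighted_mean_sd(x, w)
            # independent re-implementation of the ratio-estimator variance
            xw = np.sum(w * x) / np.sum(w)
            wbar = np.mean(w)
            sem2 = (n / ((n - 1) * (n * wbar) ** 2)) * (
                np.sum((w * x - wbar * xw) ** 2)
                - 2 * xw * np.sum((w - wbar) * (w * x - wbar * xw))
                + xw**2 * np.sum((w - wbar) ** 2)
            )
            n_eff = np.sum(w) ** 2 / np.sum(w**2)
            assert mean == pytest.approx(xw, abs=1e-12)
            assert sd == pytest.approx(np.sqrt(sem2 * n_eff), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_sd([], [])


class TestSSIg:
    @pytest.mark.parametrize(
        "profile,expected",
        [([1, 0, 0, 0], 4.0), ([1, 1, 1, 1], 2.5), ([1, 0, 0, 3], 1.75), ([0, 0, 0, 1], 1.0)],
    )
    def test_weighted_mean_of_coefficients(self, profile, expected):
        assert compute_ssig(profile) == pytest.approx(expected)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            compute_ssig([0, 0, 0, 0])

    @pytest.mark.parametrize(
        "ssig,expected", [(1.60, "cropland"), (1.85, "mixed"), (2.44, "grassland")]
    )
    def test_threshold_classification(self, ssig, expected):
        # Skylark, Linnet and Whinchat under the published thresholds
        assert classify_main_habitat(ssig) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_main_habitat(0.5)


class TestOneSampleT:
    def test_textbook_value(self):
        t, p = one_sample_t([1.0, 2.0, 3.0])
        assert t == pytest.approx(3.4641, abs=1e-4)
        ref = stats.ttest_1samp([1.0, 2.0, 3.0], 0.0)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_symmetric_values_give_zero(self):
        t, p = one_sample_t([-1.0, 1.0, -2.0, 2.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_on_random_unweighted_cases(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.normal(loc=rng.normal(), size=rng.integers(3, 30))
            t, p = one_sample_t(x)
            ref = stats.ttest_1samp(x, 0.0)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_flagged_infinite(self):
        t, p = one_sample_t([2.0, 2.0, 2.0])
        assert np.isinf(t) and p == 0.0


class TestTukeyHSD:
    def test_identical_groups(self):
        out = tukey_hsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        row = out.iloc[0]
        assert row["diff"] == pytest.approx(0.0)
        assert row["p_adj"] > 0.99

    def test_two_balanced_groups_equal_pooled_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=12), rng.normal(loc=0.8, size=12)
        out = tukey_hsd({"a": a, "b": b}).iloc[0]
        t, p = stats.ttest_ind(a, b)
        # studentized range with k = 2: q = sqrt(2) |t|
        assert out["p_adj"] == pytest.approx(p, abs=1e-6)

    def test_three_groups_match_statsmodels(self):
        rng = np.random.default_rng(6)
        groups = {g: rng.normal(loc=mu, size=n)
                  for g, mu, n in [("a", 0.0, 10), ("b", 0.5, 14), ("c", -0.3, 8)]}
        out = tukey_hsd(groups).set_index(["group1", "group2"])
        values = np.concatenate(list(groups.values()))
        labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
        ref = pairwise_tukeyhsd(values, labels)
        for (g1, g2), diff, lo, hi, p in zip(
            [("a", "b"), ("a", "c"), ("b", "c")],
            ref.meandiffs, ref.confint[:, 0], ref.confint[:, 1], ref.pvalues,
        ):
            row = out.loc[(g1, g2)]
            assert row["diff"] == pytest.approx(diff, abs=1e-9)
            assert row["lower"] == pytest.approx(lo, abs=1e-6)
            assert row["upper"] == pytest.approx(hi, abs=1e-6)
            assert row["p_adj"] == pytest.approx(p, abs=1e-4)

    def test_flat_api_with_labels(self):
        out = tukey_hsd([1.0, 2.0, 1.5, 5.0, 6.0, 5.5], ["a", "a", "a", "b", "b", "b"])
        assert len(out) == 1 and out.iloc[0]["diff"] > 0

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


@pytest.fixture(scope="module")
def fitted():
    df = make_recovery_dataset(31, n_regions=60, n_years=3)
    fit = fit_glmm(df, ["suitability", "farmland_prop"])
    cur = df.drop_duplicates("region_id")[["region_id", "suitability", "farmland_prop"]]
    for c in fb.CROPS:
        cur = cur.assign(**{c: 0.0})
    return fit, cur.reset_index(drop=True)


class TestDriverDecomposition:

    def test_future_equals_current_gives_zero_changes(self, fitted):
        fit, cur = fitted
        changes, summary = driver_decomposition(fit, cur, cur.copy())
        assert np.allclose(changes["change"], 0.0)

    def test_declining_suitability_gives_negative_climate_change(self, fitted):
        fit, cur = fitted
        fut = cur.copy()
        fut["suitability"] = cur["suitability"] * 0.5
        assert fit.params["suitability"] > 0
        changes, summary = driver_decomposition(fit, cur, fut)
        climate = summary[summary["combo"] == "climate_only"].iloc[0]
        assert climate["mean"] < 0
        untouched = changes[changes["combo"] == "land_use_only"]
        assert np.allclose(untouched["change"], 0.0)

    def test_all_drivers_equals_composed_toggles(self, fitted):
        fit, cur = fitted
        rng = np.random.default_rng(8)
        fut = cur.copy()
        fut["suitability"] = rng.uniform(size=len(cur))
        fut["farmland_prop"] = rng.uniform(size=len(cur))
        changes, _ = driver_decomposition(fit, cur, fut)
        all_d = changes[changes["combo"] == "all_drivers"]["change"].to_numpy()
        # same covariate vector assembled manually, order of toggling immaterial
        manual = cur.copy()
        manual["farmland_prop"] = fut["farmland_prop"]
        manual["suitability"] = fut["suitability"]
        from farmbird.abundance import predict_abundance

        ra_cur = predict_abundance(fit, cur)
        ra_fut = predict_abundance(fit, manual)
        np.testing.assert_allclose(all_d, symmetric_change(ra_cur, ra_fut), atol=1e-12)

    def test_unknown_combo_rejected(self, fitted):
        fit, cur = fitted
        with pytest.raises(ValueError):
            driver_decomposition(
                fit, cur, cur, combos=[DriverCombination("bad", frozenset({"volcanoes"}))]
            )

    def test_default_combo_names_match_reporting_structure(self):
        assert [c.name for c in DEFAULT_COMBOS] == [
            "climate_only", "land_use_only", "farmland_cover_only",
            "land_use_plus_cover", "all_drivers",
        ]
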