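"""Missing-data machinery: complete cases, PMM, logistic fills, chains, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import frailty_atlas as fa
from frailty_atlas.data_model import derive_age_band
from frailty_atlas.imputation import (
    ImputationConfig,
    binary_impute,
    chained_impute,
    complete_case_filter,
    direct_index_impute,
    missingness_diagnostics,
    pmm_impute,
)


class TestCompleteCaseFilter:
    def test_drops_rows_with_missing_required_items(self):
        t = pd.DataFrame({"a": [1, np.nan, 3, 4, 5], "b": [1, 2, np.nan, 4, 5]})
        out = complete_case_filter(t, ["a", "b"])
        assert len(out) == 3

    def test_identity_on_fully_observed(self):
        t = pd.DataFrame({"a": [1.0, 2, 3]})
        pd.testing.assert_frame_equal(complete_case_filter(t, ["a"]), t)

    def test_all_incomplete_warns(self):
        t = pd.DataFrame({"a": [np.nan, np.nan]})
        with pytest.warns(UserWarning, match="every row"):
            out = complete_case_filter(t, ["a"])
        assert out.empty


class TestPMM:
    def test_no_missing_is_identity(self, rng):
        target = pd.Series([1.0, 2.0, 3.0])
        out = pmm_impute(target, pd.DataFrame({"x": [1, 2, 3]}), k=1, rng=rng)
        pd.testing.assert_series_equal(out, target)

    def test_donor_membership(self, rng):
        target = pd.Series([1.0, 2.0, 3.0] * 5 + [np.nan] * 10)
        preds = pd.DataFrame({"x": np.arange(25.0)})
        out = pmm_impute(target, preds, k=3, rng=rng)
        assert set(out[15:]) <= {1.0, 2.0, 3.0}

    def test_collinear_target_matches_nearest_donor(self, rng):
        # target = 2x exactly on observed rows; with k=1 each missing entry must
        # take the donor whose predicted mean (2x) is closest -- brute-forced here.
        x = pd.Series([0.0, 1, 2, 3, 4, 5, 6, 7, 8.5, 3.2])
        target = 2.0 * x
        target.iloc[[8, 9]] = np.nan
        out = pmm_impute(target, x.to_frame("x"), k=1, rng=rng)
        donors_x, donors_y = x.iloc[:8].to_numpy(), (2.0 * x.iloc[:8]).to_numpy()
        for i in (8, 9):
            expected = donors_y[np.argmin(np.abs(donors_x - x.iloc[i]))]
            assert out.iloc[i] == expected

    def test_insufficient_donors_error(self, rng):
        target = pd.Series([1.0, np.nan, np.nan])
        with pytest.raises(ValueError, match="donors"):
            pmm_impute(target, pd.DataFrame({"x": [1, 2, 3]}), k=5, rng=rng)


class TestBinaryImpute:
    def test_degenerate_single_class(self, rng):
        target = pd.Series([1.0, 1.0, 1.0, np.nan, np.nan])
        with pytest.warns(UserWarning, match="single observed class"):
            out = binary_impute(target, pd.DataFrame({"x": range(5)}), rng)
        assert (out[3:] == 1.0).all()

    def test_predictor_free_rate_matches_prevalence(self, rng):
        p = 0.3
        observed = (rng.random(400) < p).astype(float)
        target = pd.Series(np.concatenate([observed, np.full(2000, np.nan)]))
        preds = pd.DataFrame({"c": np.ones(2400)})
        out = binary_impute(target, preds, rng)
        p_obs = observed.mean()
        rate = out[400:].mean()
        assert rate == pytest.approx(p_obs, abs=3 * np.sqrt(p_obs * (1 - p_obs) / 2000))

    def test_no_missing_unchanged(self, rng):
        target = pd.Series([0.0, 1.0, 0.0])
        pd.testing.assert_series_equal(binary_impute(target, pd.DataFrame({"x": range(3)}), rng), target)


@pytest.fixture(scope="module")
def mnar_table():
    cfg = fa.GeneratorConfig(method="instrument", n_countries=4,
                             subjects_per_country=60, seed=55)
    survey, _ = fa.generate_population(cfg)
    return fa.inject_missingness(survey, cfg)


class TestChainedImpute:

    def test_zero_missing_gives_identical_copies(self, small_instrument_population):
        _, survey, _ = small_instrument_population
        sub = survey.head(50)
        out = chained_impute(sub, ImputationConfig(m=3, iterations=2, seed=1))
        assert out.m == 3
        for d in out:
            pd.testing.assert_frame_equal(d, sub)

    def test_default_m_is_ten(self, mnar_table):
        out = chained_impute(mnar_table.head(150), ImputationConfig(iterations=2, seed=2))
        assert out.m == 10

    def test_observed_cells_never_modified(self, mnar_table):
        sub = mnar_table.head(200)
        out = chained_impute(sub, ImputationConfig(m=3, iterations=3, seed=3))
        for d in out:
            for col in out.flags.columns:
                obs = ~out.flags[col]
                pd.testing.assert_series_equal(d.loc[obs, col], sub.loc[obs, col])
            assert d.notna().all().all()

    def test_imputed_cells_vary_only_where_missing(self, mnar_table):
        sub = mnar_table.head(200)
        out = chained_impute(sub, ImputationConfig(m=3, iterations=3, seed=4))
        a, b = out.datasets[0], out.datasets[1]
        diff = a.fillna(-999) != b.fillna(-999)
        assert not diff[~out.flags].any().any()

    def test_seeded_determinism(self, mnar_table):
        sub = mnar_table.head(150)
        cfg = ImputationConfig(m=2, iterations=2, seed=11)
        o1 = chained_impute(sub, cfg)
        o2 = chained_impute(sub, cfg)
        for d1, d2 in zip(o1, o2):
            pd.testing.assert_frame_equal(d1, d2)

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            ImputationConfig(m=1)


class TestDirectIndexImpute:
    def test_no_trigger_is_identity(self, rng):
        t = pd.DataFrame({"fi": [0.1, 0.2], "gender": ["female", "male"]})
        pd.testing.assert_frame_equal(direct_index_impute(t, rng=rng), t)

    def test_imputed_fi_is_an_observed_value(self, rng):
        t = pd.DataFrame({
            "fi": [0.1, 0.3, 0.2, 0.15, 0.05, np.nan, np.nan],
            "gender": ["female"] * 7,
            "education_years": [8, 10, 12, 9, 11, 10, 12],
        })
        out = direct_index_impute(t, rng=rng)
        assert out["fi"].notna().all()
        assert set(out["fi"].iloc[5:]) <= set(t["fi"].iloc[:5])

    def test_degenerate_zero_donors(self, rng):
        t = pd.DataFrame({"fi": [0.0, 0.0, 0.0, np.nan], "education_years": [1, 2, 3, 4]})
        out = direct_index_impute(t, rng=rng)
        assert out.loc[3, "fi"] == 0.0

    def test_no_observed_donors_errors(self, rng):
        t = pd.DataFrame({"fi": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="donors"):
            direct_index_impute(t, rng=rng)


class TestMissingnessDiagnostics:
    def test_independent_missingness_gives_null_statistic(self):
        t = pd.DataFrame({
            "age_band": ["50-54"] * 100 + ["85+"] * 100,
            "x": ([1.0, 0.0] * 40 + [np.nan] * 20) * 2,
        })
        with pytest.warns(UserWarning, match="degenerate"):
            out = missingness_diagnostics(t, ["x"])  # positivity table is 1-row
        row = out[out["against"] == "age_band"].iloc[0]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert row["p_value"] == pytest.approx(1.0)

    def test_two_by_two_matches_hand_chi_square(self):
        # completeness x stratum table [[50, 90], [50, 10]]: chi2 = 38.0952...
        t = pd.DataFrame({
            "age_band": ["50-54"] * 100 + ["85+"] * 100,
            "x": [1.0, 0.0] * 25 + [np.nan] * 50 + [1.0, 0.0] * 45 + [np.nan] * 10,
        })
        with pytest.warns(UserWarning, match="degenerate"):
            out = missingness_diagnostics(t, ["x"])  # positivity table is 1-row
        row = out[out["against"] == "age_band"].iloc[0]
        hand = 200 * (50 * 10 - 50 * 90) ** 2 / (100 * 100 * 140 * 60)
        assert row["chi2"] == pytest.approx(hand, rel=1e-12)
        assert hand == pytest.approx(38.095238, rel=1e-6)

    def test_mnar_age_association_is_extreme(self):
        cfg = fa.GeneratorConfig(method="instrument", n_countries=8,
                                 subjects_per_country=200, seed=77)
        survey, _ = fa.generate_population(cfg)
        out = fa.inject_missingness(survey, cfg)
        out["age_band"] = out["reported_age"].map(derive_age_band)
        items = ["grip_strength", "fatigue", "low_activity", "appetite_loss",
                 "eating_less", "difficulty_climbing_stairs", "difficulty_walking_100m"]
        diag = missingness_diagnostics(out, items)
        age_row = diag[diag["against"] == "age_band"].iloc[0]
        assert age_row["p_value"] < 1e-5
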