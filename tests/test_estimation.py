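"""Exact CIs, prevalence tables, mixed-model fitting, Rubin pooling, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import expit

import frailty_atlas as fa
from frailty_atlas.estimation import (
    FrailtyGLMM,
    ModelSpec,
    exact_ci,
    predict_prevalence,
    prevalence_table,
    rubin_pool,
)

from conftest import make_glmm_results


def bruteforce_clopper_pearson(k, n, level=0.95):
    """Independent oracle: invert the binomial tail probabilities numerically."""
    alpha = 1 - level
    if k == 0:
        low = 0.0
    else:
        low = optimize.brentq(lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    if k == n:
        high = 1.0
    else:
        high = optimize.brentq(lambda p: stats.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    return low, high


class TestExactCI:
    def test_zero_successes(self):
        low, high = exact_ci(0, 10)
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-9)
        assert high == pytest.approx(0.3085, abs=1e-4)

    def test_three_of_ten(self):
        low, high = exact_ci(3, 10)
        assert (low, high) == pytest.approx((0.0667, 0.6525), abs=1e-4)

    def test_all_successes(self):
        low, high = exact_ci(10, 10)
        assert high == 1.0
        assert low == pytest.approx(1 - (1 - 0.025 ** (1 / 10)), abs=1e-9)

    def test_invalid_inputs(self):
        for k, n in [(-1, 10), (11, 10), (0, 0)]:
            with pytest.raises(ValueError):
                exact_ci(k, n)

    def test_matches_bruteforce_inversion_everywhere(self):
        for n in range(1, 26):
            for k in range(n + 1):
                got = exact_ci(k, n)
                want = bruteforce_clopper_pearson(k, n)
                assert got == pytest.approx(want, abs=1e-7), (k, n)


class TestPrevalenceTable:
    def _table(self, frail):
        return pd.DataFrame({
            "country": "AT", "age_band": "70-74", "gender": "female",
            "frail": frail,
        })

    def test_single_dataset(self):
        out = prevalence_table(self._table([1.0] * 3 + [0.0] * 7))
        row = out.iloc[0]
        assert row["prevalence"] == pytest.approx(0.3)
        assert (row["ci_low"], row["ci_high"]) == pytest.approx((0.0667, 0.6525), abs=1e-4)

    def test_identical_datasets_match_single(self):
        t = self._table([1.0] * 3 + [0.0] * 7)
        one = prevalence_table(t)
        two = prevalence_table([t, t.copy()])
        pd.testing.assert_frame_equal(one, two)

    def test_average_over_imputations(self):
        a = self._table([1.0] * 2 + [0.0] * 8)
        b = self._table([1.0] * 4 + [0.0] * 6)
        out = prevalence_table([a, b])
        assert out.iloc[0]["prevalence"] == pytest.approx(0.3)

    def test_unclassified_rows_ignored(self):
        out = prevalence_table(self._table([1.0, 0.0, np.nan]))
        assert out.iloc[0]["n"] == 2


class TestRubinPool:
    def test_hand_evaluated_formulas(self):
        fits = [make_glmm_results([q, q], [0.2, 0.2]) for q in (1.0, 1.2, 1.4)]
        pooled = rubin_pool(fits)
        assert pooled.params.iloc[0] == pytest.approx(1.2)
        assert pooled.W.iloc[0] == pytest.approx(0.04)
        assert pooled.B.iloc[0] == pytest.approx(0.04)
        assert pooled.T.iloc[0] == pytest.approx(0.04 + (4 / 3) * 0.04)
        assert pooled.bse.iloc[0] == pytest.approx(np.sqrt(0.09333333), abs=1e-6)

    def test_identical_fits_have_zero_between_variance(self):
        fits = [make_glmm_results([0.5, -1.0], [0.1, 0.2])] * 4
        pooled = rubin_pool(fits)
        assert (pooled.B == 0).all()
        pd.testing.assert_series_equal(pooled.T, pooled.W, check_names=False)
        assert pooled.params.iloc[1] == -1.0
        assert pooled.bse.iloc[1] == pytest.approx(0.2)

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError, match="m >= 2"):
            rubin_pool([make_glmm_results([1.0, 2.0], [0.1, 0.1])])

    def test_term_mismatch_rejected(self):
        a = make_glmm_results([1.0, 2.0], [0.1, 0.1], terms=("a", "b"))
        b = make_glmm_results([1.0, 2.0], [0.1, 0.1], terms=("a", "c"))
        with pytest.raises(ValueError, match="term sets"):
            rubin_pool([a, b])

    def test_total_variance_dominates_within(self, rng):
        for _ in range(20):
            fits = [
                make_glmm_results(rng.normal(size=2), rng.uniform(0.05, 0.5, size=2))
                for _ in range(int(rng.integers(2, 6)))
            ]
            pooled = rubin_pool(fits)
            assert (pooled.T >= pooled.W - 1e-12).all()


@pytest.fixture(scope="module")
def coeffs():
    return fa.coefficient_set("instrument_mi")


class TestPredictPrevalence:

    def test_reference_cell(self, coeffs):
        cells = pd.DataFrame({"gender": ["female"], "age_band": ["50-54"], "gdp_kEUR": [0.0]})
        assert predict_prevalence(coeffs, cells).iloc[0] == pytest.approx(0.0441, abs=1e-4)

    def test_worked_example_75_79(self, coeffs):
        cells = pd.DataFrame({"gender": ["female"], "age_band": ["75-79"], "gdp_kEUR": [30.0]})
        expected = expit(-3.0769 + 2.45 + 30 * (-0.0160 - 0.0211))
        got = predict_prevalence(coeffs, cells).iloc[0]
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.1495, abs=2e-4)

    def test_decreasing_in_gdp_where_total_slope_negative(self, coeffs):
        cells = pd.DataFrame({
            "gender": "female", "age_band": "70-74", "gdp_kEUR": np.linspace(2, 50, 20),
        })
        p = predict_prevalence(coeffs, cells)
        assert (np.diff(p) < 0).all()

    def test_increasing_across_age_bands(self, coeffs):
        from frailty_atlas.data_model import AGE_BAND_LABELS

        for gdp in (5.0, 15.0, 25.0):
            for gender in ("female", "male"):
                cells = pd.DataFrame({
                    "gender": gender, "age_band": list(AGE_BAND_LABELS), "gdp_kEUR": gdp,
                })
                p = predict_prevalence(coeffs, cells)
                assert (np.diff(p) > 0).all(), (gender, gdp)

    def test_gdp_slope_most_negative_in_eighth_decade(self, coeffs):
        from frailty_atlas.data_model import AGE_BAND_LABELS
        from frailty_atlas.estimation import band_term

        slopes = {"50-54": coeffs["gdp"]}
        for band in AGE_BAND_LABELS[1:]:
            slopes[band] = coeffs["gdp"] + coeffs[f"{band_term(band)}:gdp"]
        assert min(slopes, key=slopes.get) == "70-74"

    def test_unknown_band_rejected(self, coeffs):
        cells = pd.DataFrame({"gender": ["female"], "age_band": ["40-44"], "gdp_kEUR": [1.0]})
        with pytest.raises(KeyError):
            predict_prevalence(coeffs, cells)

    def test_marginal_prediction_exceeds_conditional_below_half(self, coeffs):
        # averaging a convex region of the inverse logit raises the mean
        cells = pd.DataFrame({"gender": ["female"], "age_band": ["60-64"], "gdp_kEUR": [20.0]})
        cond = predict_prevalence(coeffs, cells).iloc[0]
        marg = predict_prevalence(coeffs, cells, marginal=True, sigma2_country=1.0, seed=5).iloc[0]
        assert marg > cond


class TestFrailtyGLMM:
    def test_degenerate_outcome_rejected(self):
        t = pd.DataFrame({
            "frail": [0.0] * 10, "gender": ["female"] * 10, "age_band": ["50-54"] * 10,
            "gdp_kEUR": 10.0, "subject_id": [str(i) for i in range(10)], "country": "AT",
        })
        with pytest.raises(ValueError, match="degenerate"):
            FrailtyGLMM(t)

    def test_zero_variance_matches_ordinary_logistic(self, zero_variance_fits):
        """With sigma = 0 and one wave per subject the mixed fit agrees with the
        ordinary-logistic oracle on every fixed effect."""
        mixed, ordinary = zero_variance_fits
        assert mixed.converged and ordinary.converged
        for term in ordinary.params.index:
            assert abs(mixed.params[term] - ordinary.params[term]) <= 2 * ordinary.bse[term]
        assert mixed.sigma2_subject < 0.5
        assert mixed.sigma2_country < 0.5

    def test_summary_lists_all_terms(self, zero_variance_fits):
        mixed, _ = zero_variance_fits
        text = mixed.summary()
        for term in ModelSpec().terms:
            assert term in text
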