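"""Shared fixtures: small synthetic cohorts and one expensive reference fit."""

import numpy as np
import pandas as pd
import pytest

import frailty_atlas as fa
from frailty_atlas.instrument import score_instrument_table


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_instrument_population():
    """Complete (no-missingness) instrument cohort, 6 countries x 60 x 2 waves."""
    config = fa.GeneratorConfig(
        method="instrument", n_countries=6, subjects_per_country=60, seed=101
    )
    survey, truth = fa.generate_population(config)
    return config, survey, truth


@pytest.fixture(scope="session")
def small_index_population():
    """Complete index-method cohort with the index-MI coefficient defaults."""
    config = fa.GeneratorConfig(
        method="index",
        coefficient_set_name="index_mi",
        n_countries=6,
        subjects_per_country=60,
        seed=202,
    )
    survey, truth = fa.generate_population(config)
    return config, survey, truth


@pytest.fixture(scope="session")
def zero_variance_fits():
    """lme4 and ordinary-logistic fits of the same sigma=0, single-wave cohort.

    With no random-effect variance and one observation per subject the mixed
    model and ordinary logistic regression estimate the same population model;
    computed once for both the oracle-equivalence unit test and the acceptance
    check.
    """
    config = fa.GeneratorConfig(
        method="instrument",
        n_countries=12,
        subjects_per_country=150,
        waves_per_subject=1,
        sigma_subject=0.0,
        sigma_country=0.0,
        seed=303,
    )
    survey, _ = fa.generate_population(config)
    scored = score_instrument_table(survey)
    model = fa.FrailtyGLMM(scored)
    return model.fit(backend="lme4"), model.fit(backend="ordinary")


def make_glmm_results(estimates, ses, terms=("a", "b")):
    """Hand-built results objects for pooling tests."""
    from frailty_atlas.estimation import GLMMResults, ModelSpec

    idx = pd.Index(list(terms))
    return GLMMResults(
        params=pd.Series(list(estimates), index=idx),
        bse=pd.Series(list(ses), index=idx),
        vc={"subject": 1.0, "country": 0.1},
        converged=True,
        nobs=100,
        spec=ModelSpec(),
        backend="test",
    )
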