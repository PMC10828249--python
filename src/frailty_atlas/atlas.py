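"""Frailty-atlas assembly and the end-to-end pipeline.

The atlas is a long-format table with one row per country x 5-year age band x
gender (x frailty method x missing-data approach x GDP variant): observed
prevalence with its exact confidence interval where survey data exist, and the
model-predicted prevalence for every country — the prediction being the only
estimate available for the 13 catalog countries without survey participation.

:func:`run_pipeline` chains the stages on synthetic data: simulate -> inject
missingness -> eligibility filter -> (multiple imputation | complete-case) ->
score -> stratified prevalence -> per-imputation model fits -> Rubin pooling ->
prediction -> atlas, writing all intermediates plus a manifest.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import imputation as imp_mod
from . import index as fi_mod
from . import instrument as inst_mod
from . import synthetic
from .data_model import (
    AGE_BAND_LABELS,
    AnalysisConfig,
    default_country_catalog,
    filter_eligible,
)
from .estimation import (
    FrailtyGLMM,
    GLMMResults,
    ModelSpec,
    PooledResults,
    predict_prevalence,
    prevalence_table,
    rubin_pool,
)

__all__ = ["ATLAS_COLUMNS", "build_atlas", "run_pipeline", "fit_to_dict"]

logger = logging.getLogger(__name__)

ATLAS_COLUMNS = [
    "country", "iso2", "share_participant", "method", "missing_approach",
    "gdp_variant", "age_band", "gender", "n", "n_frail",
    "prev_obs", "ci_low", "ci_high", "prev_pred", "gdp_kEUR",
]


def build_atlas(
    observed: pd.DataFrame | None,
    fit,
    country_attrs: pd.DataFrame | None = None,
    method: str = "instrument",
    missing_approach: str = "multiple_imputation",
    gdp_variant: str = "ppp",
) -> pd.DataFrame:
    """Join observed stratum prevalence with model predictions per country.

    ``observed`` is a :func:`~frailty_atlas.estimation.prevalence_table` output
    (strata country, age_band, gender; countries as ISO-2 codes); ``fit`` is a
    fitted/pooled results object or coefficient mapping used for prediction.
    Countries without a usable GDP value are excluded with a warning;
    non-participant countries carry predictions only.
    """
    if fit is None:
        raise ValueError("a fitted model is required: observed-only atlas is not defined")
    attrs = default_country_catalog() if country_attrs is None else country_attrs
    gdp_col = "gdp_kEUR_ppp" if gdp_variant == "ppp" else "gdp_kEUR"
    rows = []
    for _, c in attrs.iterrows():
        gdp = c.get(gdp_col, np.nan)
        if pd.isna(gdp) or gdp <= 0:
            warnings.warn(f"country {c['country']} has no usable GDP; excluded", stacklevel=2)
            continue
        for band in AGE_BAND_LABELS:
            for gender in ("female", "male"):
                rows.append({
                    "country": c.get("name", c["country"]),
                    "iso2": c["country"],
                    "share_participant": bool(c.get("share_participant", True)),
                    "method": method,
                    "missing_approach": missing_approach,
                    "gdp_variant": gdp_variant,
                    "age_band": band,
                    "gender": gender,
                    "gdp_kEUR": float(gdp),
                })
    atlas = pd.DataFrame(rows)
    cells = atlas[["gender", "age_band", "gdp_kEUR"]]
    atlas["prev_pred"] = predict_prevalence(fit, cells).to_numpy()
    if observed is not None and len(observed):
        obs = observed.rename(
            columns={"prevalence": "prev_obs", "country": "iso2"}
        )[["iso2", "age_band", "gender", "n", "n_frail", "prev_obs", "ci_low", "ci_high"]]
        atlas = atlas.merge(obs, on=["iso2", "age_band", "gender"], how="left")
    else:
        for col in ("n", "n_frail", "prev_obs", "ci_low", "ci_high"):
            atlas[col] = np.nan
    return atlas[ATLAS_COLUMNS]


# ------------------------------------------------------------------- pipeline

_INSTRUMENT_ITEMS = [
    "grip_strength", "fatigue", "appetite_loss", "eating_less",
    "difficulty_climbing_stairs", "difficulty_walking_100m", "low_activity",
]


def _required_items(method: str, catalog: fi_mod.DeficitCatalog) -> list[str]:
    return catalog.raw_columns() if method == "index" else list(_INSTRUMENT_ITEMS)


def _score(table: pd.DataFrame, method: str, catalog, weights, use_wave: bool) -> pd.DataFrame:
    if method == "index":
        return fi_mod.score_index_table(table, catalog, use_wave=use_wave)
    return inst_mod.score_instrument_table(table, weights)


def fit_to_dict(fit) -> dict:
    """JSON-serialisable summary of a fitted or pooled model."""
    out = {
        "terms": list(fit.params.index),
        "estimates": [float(v) for v in fit.params],
        "se": [float(v) for v in fit.bse],
        "variances": {k: float(v) for k, v in fit.vc.items()},
    }
    if isinstance(fit, PooledResults):
        out |= {"m": fit.m, "df": [float(v) for v in fit.df]}
    if isinstance(fit, GLMMResults):
        out |= {"m": 1, "converged": bool(fit.converged), "backend": fit.backend}
    return out


def run_pipeline(config: Mapping, outdir: str | Path | None = None) -> dict:
    """Execute the full synthetic-data analysis; returns the artifact bundle.

    ``config`` keys (all optional): ``method``, ``missing_approach``, ``seed``,
    ``m``, ``backend``, ``generator`` (GeneratorConfig fields), ``imputation``
    (iterations, k). When ``outdir`` is given, writes survey/truth/prevalence/
    atlas CSVs, fit.json and manifest.json there.
    """
    method = config.get("method", "instrument")
    approach = config.get("missing_approach", "multiple_imputation")
    seed = int(config.get("seed", 0))
    m = int(config.get("m", 10))
    backend = config.get("backend", "lme4")
    stage = "simulate"
    try:
        gen_kw = dict(config.get("generator", {}))
        gen_kw.setdefault("method", method)
        gen_kw.setdefault(
            "coefficient_set_name",
            f"{method}_{'mi' if approach == 'multiple_imputation' else 'cc'}",
        )
        gen_kw["seed"] = seed
        gen_config = synthetic.GeneratorConfig(**gen_kw)
        survey, truth = synthetic.generate_population(gen_config)
        survey = synthetic.inject_missingness(survey, gen_config, seed=seed + 1)

        stage = "filter"
        analysis = AnalysisConfig(method=method, missing_approach=approach,
                                  m=m, seed=seed)
        survey = filter_eligible(survey, analysis)
        catalog = fi_mod.default_catalog()
        weights = inst_mod.default_weights()
        required = _required_items(method, catalog)

        stage = "impute" if approach == "multiple_imputation" else "complete_case"
        if approach == "complete_case":
            cc = imp_mod.complete_case_filter(survey, required)
            scored = [_score(cc, method, catalog, weights, use_wave=True)]
        else:
            imp_kw = dict(config.get("imputation", {}))
            imp_config = imp_mod.ImputationConfig(m=m, seed=seed + 2, **imp_kw)
            completed = imp_mod.chained_impute(survey, imp_config)
            scored = []
            for d in completed:
                sd = _score(d, method, catalog, weights, use_wave=False)
                if method == "index" and sd["fi"].isna().any():
                    sd = imp_mod.direct_index_impute(sd, rng=np.random.default_rng(seed + 3))
                    sd["frail"] = (sd["fi"] >= fi_mod.FRAILTY_INDEX_THRESHOLD).astype(float)
                scored.append(sd)

        stage = "prevalence"
        prevalence = prevalence_table(scored, strata=("country", "age_band", "gender"))

        stage = "fit"
        spec = ModelSpec(gdp_col="gdp_kEUR")
        fits = [FrailtyGLMM(s, spec).fit(backend=backend) for s in scored]
        pooled = rubin_pool(fits, n_com=fits[0].nobs) if len(fits) >= 2 else fits[0]

        stage = "atlas"
        atlas = build_atlas(
            prevalence, pooled,
            method=method, missing_approach=approach,
            gdp_variant="ppp" if config.get("ppp", True) else "market",
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "seed": seed, "method": method, "missing_approach": approach,
        "m": len(scored), "backend": backend,
        "n_surveys": int(len(survey)), "stages": "simulate|filter|" +
        ("impute" if approach == "multiple_imputation" else "complete_case") +
        "|prevalence|fit|pool|predict|atlas",
    }
    bundle = {
        "survey": survey, "truth": truth, "scored": scored,
        "prevalence": prevalence, "fits": fits, "pooled": pooled,
        "atlas": atlas, "manifest": manifest,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        survey.to_csv(outdir / "survey.csv", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)
        prevalence.to_csv(outdir / "prevalence.csv", index=False)
        atlas.to_csv(outdir / "atlas.csv", index=False)
        (outdir / "fit.json").write_text(json.dumps(fit_to_dict(pooled), indent=2))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
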