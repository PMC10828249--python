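"""Synthetic SHARE-like cohorts with known frailty truth.

Real SHARE microdata is restricted-access, so every downstream stage is
exercised on synthetic person-wave tables generated here. Generation is
two-stage:

1. draw each person-wave's binary frailty state ``F`` from the mixed logistic
   model itself — linear predictor from the published coefficient set (gender x
   age band, GDP/capita x age band, thousand EUR) plus subject and country
   random intercepts — so the estimation model is exactly true for the scored
   labels and parameter recovery is a sharp test;
2. render survey item responses *conditional on F* such that the corresponding
   scorer (40-item index or 5-component instrument) reproduces F exactly on
   complete data.

Missingness is injected afterwards (:func:`inject_missingness`) with
probability increasing in age band and in deficit-positivity of the masked
value itself — the missing-not-at-random pattern observed in the survey, where
older and frailer respondents have more incomplete frailty data.

Defaults emulate the study conditions: 29 observed countries with their
catalog GDP values, 44.5% male, age-band mix from the published cohort table,
biennial waves, sigma_subject = 1.0 and sigma_country = 0.3 (the source
reports no variance components; these are stated assumptions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .data_model import AGE_BAND_LABELS, derive_age_band, default_country_catalog
from .estimation import ModelSpec, band_term
from . import index as fi_mod
from . import instrument as inst_mod

__all__ = [
    "coefficient_set",
    "coefficient_sets",
    "MNARConfig",
    "GeneratorConfig",
    "linear_predictor",
    "generate_population",
    "render_items",
    "inject_missingness",
]

#: Age-band frequencies of the observed cohort (instrument full sample), in %.
AGE_BAND_WEIGHTS = (10.62, 15.50, 17.14, 16.47, 14.17, 11.34, 8.10, 6.66)

MALE_FRACTION = 0.445

_ALLOWED_WAVES = {"instrument": (1, 2, 4, 6, 8), "index": (1, 2, 4, 5, 6, 8)}

_WAVE_YEAR = {w: 2004 + 2 * (w - 1) for w in range(1, 9)}


def coefficient_sets() -> dict:
    """All shipped published coefficient sets, keyed method_approach."""
    with resources.files("frailty_atlas.data").joinpath("model_coefficients.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return raw["sets"]


def coefficient_set(name: str = "instrument_mi") -> dict[str, float]:
    """One named fixed-effect coefficient set (e.g. ``instrument_mi``)."""
    sets = coefficient_sets()
    if name not in sets:
        raise KeyError(f"unknown coefficient set {name!r}; have {sorted(sets)}")
    return {k: float(v) for k, v in sets[name]["coefficients"].items()}


def linear_predictor(covariates: Mapping, coefficients: Mapping[str, float]) -> float:
    """Log-odds of frailty for one (gender, age band, GDP) cell.

    eta = b0 + b_male*[male] + b_band + b_band:male*[male]
        + (g0 + g_band) * gdp_kEUR,
    with female and the 50-54 band as reference levels contributing zero.
    """
    terms = set(ModelSpec().terms)
    unknown = set(coefficients) - terms
    if unknown:
        raise KeyError(f"unknown coefficient names {sorted(unknown)}")
    missing = terms - set(coefficients)
    if missing:
        raise KeyError(f"incomplete coefficient set; missing {sorted(missing)}")
    gender = covariates["gender"]
    if gender not in ("female", "male"):
        raise ValueError(f"unknown gender {gender!r}")
    male = float(gender == "male")
    band = covariates["age_band"]
    if band not in AGE_BAND_LABELS:
        raise KeyError(f"unknown age band {band!r}")
    gdp = float(covariates["gdp_kEUR"])
    c = coefficients
    eta = c["intercept"] + c["male"] * male
    gdp_slope = c["gdp"]
    if band != AGE_BAND_LABELS[0]:
        bt = band_term(band)
        eta += c[bt] + c[f"{bt}:male"] * male
        gdp_slope += c[f"{bt}:gdp"]
    return eta + gdp_slope * gdp


@dataclass(frozen=True)
class MNARConfig:
    """Item-level missingness model on the log-odds scale.

    P(missing) = expit(base_logit + band_offset[age band] + positivity_offset
    * [masked value is deficit-positive]). Defaults give roughly 4% missingness
    in the youngest band rising to ~14% (deficit-negative values) in the 85+
    band, higher again for deficit-positive values.
    """

    base_logit: float = -3.2
    band_offsets: tuple = tuple(np.linspace(0.0, 1.4, 8).round(4))
    positivity_offset: float = 0.8

    def prob(self, band: str, positive: bool) -> float:
        off = self.band_offsets[AGE_BAND_LABELS.index(band)]
        return float(expit(self.base_logit + off + self.positivity_offset * positive))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort generator."""

    method: str = "instrument"
    n_countries: int = 29
    subjects_per_country: int = 150
    waves_per_subject: int = 2
    coefficients: Mapping[str, float] | None = None
    coefficient_set_name: str = "instrument_mi"
    gdp_kEUR: Mapping[str, float] | None = None  # per-country override
    gdp_range: tuple[float, float] = (2.0, 45.0)
    sigma_subject: float = 1.0
    sigma_country: float = 0.3
    male_fraction: float = MALE_FRACTION
    age_band_weights: tuple = AGE_BAND_WEIGHTS
    mnar: MNARConfig = field(default_factory=MNARConfig)
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("instrument", "index"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.subjects_per_country < 1 or self.waves_per_subject < 1:
            raise ValueError("subjects_per_country and waves_per_subject must be >= 1")
        if self.sigma_subject < 0 or self.sigma_country < 0:
            raise ValueError("random-intercept standard deviations must be >= 0")
        if self.coefficients is not None:
            # validates names against the model term set
            linear_predictor(
                {"gender": "female", "age_band": "50-54", "gdp_kEUR": 0.0},
                self.coefficients,
            )

    def resolved_coefficients(self) -> dict[str, float]:
        if self.coefficients is not None:
            return dict(self.coefficients)
        return coefficient_set(self.coefficient_set_name)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        if hasattr(path, "read"):
            raw = yaml.safe_load(path)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        if "mnar" in raw:
            mn = raw.pop("mnar")
            raw["mnar"] = MNARConfig(
                base_logit=float(mn.get("base_logit", -3.2)),
                band_offsets=tuple(mn.get("band_offsets", MNARConfig().band_offsets)),
                positivity_offset=float(mn.get("positivity_offset", 0.8)),
            )
        for key in ("age_band_weights", "gdp_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _country_gdp(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, float]:
    if config.gdp_kEUR is not None:
        items = list(config.gdp_kEUR.items())[: config.n_countries]
        return dict(items)
    cat = default_country_catalog()
    share = cat[cat["share_participant"]]
    out: dict[str, float] = {}
    for _, row in share.head(config.n_countries).iterrows():
        out[str(row["country"])] = float(row["gdp_kEUR_ppp"])
    extra = config.n_countries - len(out)
    for i in range(max(extra, 0)):
        out[f"Z{i:02d}"] = float(rng.uniform(*config.gdp_range))
    return out


def _draw_age(rng: np.random.Generator, weights) -> int:
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    i = int(rng.choice(len(AGE_BAND_LABELS), p=p))
    lower = 50 + 5 * i
    upper = lower + 5 if i < 7 else 96 - lower + lower  # 85+ spans 85..95
    if i == 7:
        return int(rng.integers(85, 96))
    return int(rng.integers(lower, upper))


# ------------------------------------------------------------- item rendering

_SPH_LEVEL_P = {  # frail-leaning vs healthy-leaning 5-level distributions
    1: (0.05, 0.15, 0.30, 0.30, 0.20),
    0: (0.30, 0.35, 0.25, 0.08, 0.02),
}


def _render_index_items(F: int, rng: np.random.Generator,
                        catalog: fi_mod.DeficitCatalog) -> dict:
    """Item values whose 40-item mean crosses 0.25 exactly when F = 1."""
    level = int(rng.choice(5, p=_SPH_LEVEL_P[F])) + 1
    s = (level - 1) * 0.25
    # need n_pos binary positives with n_pos + s >= 10 iff F = 1
    t = math.ceil(10 - s - 1e-9)
    if F:
        n_pos = min(t + int(rng.binomial(10, 0.25)), 39)
    else:
        n_pos = int(rng.binomial(t - 1, 0.22))
    binary_items = [it for it in catalog.items if it.value_type != "ordinal5"]
    pos_idx = set(rng.choice(len(binary_items), size=n_pos, replace=False))
    rec: dict = {"self_perceived_health": level}
    for j, item in enumerate(binary_items):
        val = int(j in pos_idx)
        if item.value_type == "composite_any":
            if val:
                pick = int(rng.integers(3))  # which sub-items carry the positive
                rec[item.components[0]] = int(pick in (0, 2))
                rec[item.components[1]] = int(pick in (1, 2))
            else:
                for c in item.components:
                    rec[c] = 0
        else:
            rec[item.name] = val
    return rec


_GRIP_MEAN = {"female": 26.0, "male": 42.0}
_GRIP_SD = {"female": 6.0, "male": 8.0}


def _instrument_score(rec: dict, gender: str, weights) -> str:
    comps = inst_mod.extract_components(rec)
    score = inst_mod.discrete_factor_score(comps, gender, weights)
    return inst_mod.classify_instrument(score, gender, weights)


def _render_instrument_items(F: int, gender: str, rng: np.random.Generator,
                             weights) -> dict:
    """Component values that the weighted scorer classifies exactly as F."""
    p_def = 0.55 if F else 0.10
    grip = rng.normal(_GRIP_MEAN[gender] - 8.0 * F, _GRIP_SD[gender])
    grip = float(np.clip(grip, 1.0, 70.0))

    def expand(fatigue, appetite, mobility, activity, grip):
        rec = {"fatigue": fatigue, "low_activity": activity, "grip_strength": round(grip, 1)}
        for comp, cols in inst_mod.COMPONENT_SOURCES.items():
            val = appetite if comp == "appetite_loss" else mobility
            if val:
                pick = int(rng.integers(3))
                rec[cols[0]] = int(pick in (0, 2))
                rec[cols[1]] = int(pick in (1, 2))
            else:
                rec[cols[0]] = rec[cols[1]] = 0
        return rec

    for _ in range(8):  # biased rejection sampling
        vals = [int(rng.random() < p_def) for _ in range(4)]
        rec = expand(*vals, grip)
        if _instrument_score(rec, gender, weights) == ("frail" if F else "non_frail"):
            return rec
        grip = float(np.clip(grip + (-4.0 if F else 4.0), 1.0, 70.0))
    # deterministic fallback: saturate deficits and push grip to the extreme
    if F:
        rec = expand(1, 1, 1, 1, 1.0)
    else:
        rec = expand(0, 0, 0, 0, 70.0)
    if _instrument_score(rec, gender, weights) != ("frail" if F else "non_frail"):
        raise ValueError("weight set cannot represent both frailty classes")
    return rec


def render_items(F: int, method: str, rng: np.random.Generator,
                 gender: str = "female",
                 catalog: fi_mod.DeficitCatalog | None = None,
                 weights: inst_mod.InstrumentWeightSet | None = None) -> dict:
    """Render a full item vector consistent with the frailty state ``F``."""
    if F not in (0, 1):
        raise ValueError(f"F must be 0/1, got {F!r}")
    if method == "index":
        return _render_index_items(int(F), rng, catalog or fi_mod.default_catalog())
    if method == "instrument":
        return _render_instrument_items(
            int(F), gender, rng, weights or inst_mod.default_weights()
        )
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------- population

def generate_population(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a complete synthetic survey table and its truth ledger.

    Returns ``(survey, truth)``: ``survey`` is a person-wave table with
    demographics, auxiliaries and fully observed frailty items (apply
    :func:`inject_missingness` for the missing-data study); ``truth`` carries
    per row the linear predictor, both random intercepts and the true state
    ``F``. Reproducible from ``seed`` (default: the config's seed).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    coeffs = config.resolved_coefficients()
    gdp_by_country = _country_gdp(config, rng)
    waves = _ALLOWED_WAVES[config.method][: config.waves_per_subject]
    if len(waves) < config.waves_per_subject:
        raise ValueError("waves_per_subject exceeds the allowed wave set")
    catalog = fi_mod.default_catalog() if config.method == "index" else None
    weights = inst_mod.default_weights() if config.method == "instrument" else None

    survey_rows: list[dict] = []
    truth_rows: list[dict] = []
    for country, gdp in gdp_by_country.items():
        v = rng.normal(0.0, config.sigma_country)
        for si in range(config.subjects_per_country):
            sid = f"{country}{si:05d}"
            u = rng.normal(0.0, config.sigma_subject)
            gender = "male" if rng.random() < config.male_fraction else "female"
            age0 = _draw_age(rng, config.age_band_weights)
            edu = int(np.clip(round(rng.normal(11.0, 3.5)), 0, 25))
            living = rng.choice(
                ["alone", "with_partner", "unknown"], p=(0.14, 0.31, 0.55)
            )
            year0 = _WAVE_YEAR[waves[0]]
            for wave in waves:
                year = _WAVE_YEAR[wave]
                age = age0 + (year - year0)
                band = derive_age_band(age)
                eta = linear_predictor(
                    {"gender": gender, "age_band": band, "gdp_kEUR": gdp}, coeffs
                )
                F = int(rng.random() < expit(eta + u + v))
                items = render_items(
                    F, config.method, rng, gender=gender, catalog=catalog, weights=weights
                )
                row = {
                    "subject_id": sid,
                    "country": country,
                    "wave": wave,
                    "survey_year": year,
                    "reported_age": age,
                    "gender": gender,
                    "education_years": edu,
                    "living_with_partner": living,
                    "gdp_kEUR": gdp,
                    **items,
                }
                if config.method == "instrument":
                    # auxiliary self-perceived health for imputation models
                    row["self_perceived_health"] = int(rng.choice(5, p=_SPH_LEVEL_P[F])) + 1
                if config.method == "index":
                    p_drug = 0.4 if items.get("osteoporosis") == 1 else 0.03
                    row["osteoporosis_drugs"] = int(rng.random() < p_drug)
                survey_rows.append(row)
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "country": country,
                        "wave": wave,
                        "eta": eta,
                        "u_subject": u,
                        "v_country": v,
                        "F": F,
                    }
                )
    survey = pd.DataFrame(survey_rows)
    truth = pd.DataFrame(truth_rows)
    return survey, truth


# --------------------------------------------------------------- missingness

def _item_columns(method: str, catalog: fi_mod.DeficitCatalog | None = None) -> list[str]:
    if method == "index":
        return (catalog or fi_mod.default_catalog()).raw_columns()
    return [
        "grip_strength",
        "fatigue",
        "appetite_loss",
        "eating_less",
        "difficulty_climbing_stairs",
        "difficulty_walking_100m",
        "low_activity",
    ]


def _positive(col: str, value, gender: str, cutoffs) -> bool:
    if pd.isna(value):
        return False
    if col == "self_perceived_health":
        return int(value) >= 4
    if col == "grip_strength":
        return float(value) < float(cutoffs[gender])
    return float(value) == 1.0


def inject_missingness(
    table: pd.DataFrame,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mask frailty item cells missing-not-at-random; truth is untouched.

    Per item cell, missingness log-odds are base + age-band offset +
    positivity offset if the (to-be-masked) value is deficit-positive.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    mnar = config.mnar
    cutoffs = (inst_mod.default_weights().fried_cutoffs or {"female": 20.0, "male": 32.0})
    cols = [c for c in _item_columns(config.method) if c in table.columns]
    if config.method == "index":
        cols = [c for c in cols if c != "self_perceived_health"] + (
            ["self_perceived_health"] if "self_perceived_health" in table else []
        )
    out = table.copy()
    bands = out["reported_age"].map(derive_age_band)
    genders = out["gender"]
    for col in cols:
        vals = out[col]
        probs = np.array(
            [
                mnar.prob(b, _positive(col, v, g, cutoffs))
                for b, v, g in zip(bands, vals, genders)
            ]
        )
        mask = rng.random(len(out)) < probs
        if mask.any():
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out
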