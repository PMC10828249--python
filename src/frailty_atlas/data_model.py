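"""Core survey-table handling: eligibility filters, derived variables, country data.

The analysis operates on a long-format person-wave table (one row per completed
interview of one subject in one biennial survey wave) together with a country
attribute table carrying GDP per capita, averaged over 2000-2004 and expressed in
thousand EUR (market prices or PPP-adjusted).

Conventions fixed here and relied on everywhere else:

* ages derived from dates are completed years (floor);
* 5-year age bands are closed-left / open-right, ``[50, 55) ... [80, 85)``, with a
  terminal open band ``85+``; every resolved age >= 50 falls in exactly one band;
* missing values are represented as NaN / ``None`` (empty cells in CSV).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BAND_LABELS",
    "AgeBand",
    "AGE_BANDS",
    "AnalysisConfig",
    "resolve_age",
    "resolve_age_column",
    "derive_age_band",
    "carry_forward_education",
    "education_quartiles",
    "average_gdp",
    "filter_eligible",
    "load_survey_table",
    "write_survey_table",
    "load_country_attributes",
    "default_country_catalog",
    "country_code",
]

logger = logging.getLogger(__name__)

GENDERS = ("female", "male")

AGE_BAND_LABELS = (
    "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+",
)


@dataclass(frozen=True)
class AgeBand:
    """One 5-year age band; ``upper`` is ``None`` for the open-ended 85+ band."""

    label: str
    lower: int
    upper: int | None

    def contains(self, age: float) -> bool:
        if age < self.lower:
            return False
        return self.upper is None or age < self.upper


AGE_BANDS: tuple[AgeBand, ...] = tuple(
    AgeBand(label, 50 + 5 * i, 50 + 5 * (i + 1) if label != "85+" else None)
    for i, label in enumerate(AGE_BAND_LABELS)
)


def derive_age_band(age: float) -> str:
    """Map a resolved age (years, >= 50) to its 5-year band label."""
    if not np.isfinite(age) or age < 50:
        raise ValueError(f"age {age!r} is below the 50-year inclusion threshold")
    for band in AGE_BANDS:
        if band.contains(age):
            return band.label
    raise AssertionError("unreachable: bands partition [50, inf)")


# --------------------------------------------------------------------------- ages

def _floor_year_diff(birth: date, survey: date) -> int:
    years = survey.year - birth.year
    if (survey.month, survey.day) < (birth.month, birth.day):
        years -= 1
    return years


def resolve_age(record) -> float:
    """Resolve a subject's age at interview from the first available source.

    Sources, in priority order: the reported age at interview, the age in the
    survey year, and the difference of survey date and birth date (completed
    years). Returns NaN when none is available; such records are removed by
    :func:`filter_eligible`.
    """
    reported = record.get("reported_age")
    if reported is not None and not pd.isna(reported):
        return float(reported)
    in_year = record.get("age_in_survey_year")
    if in_year is not None and not pd.isna(in_year):
        return float(in_year)
    birth, survey = record.get("birth_date"), record.get("survey_date")
    if birth is not None and survey is not None and not pd.isna(birth) and not pd.isna(survey):
        birth = pd.Timestamp(birth).date()
        survey = pd.Timestamp(survey).date()
        return float(_floor_year_diff(birth, survey))
    return float("nan")


def resolve_age_column(table: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`resolve_age` over a survey table."""
    out = pd.Series(np.nan, index=table.index, dtype=float)
    if "reported_age" in table:
        out = pd.to_numeric(table["reported_age"], errors="coerce")
    if "age_in_survey_year" in table:
        fallback = pd.to_numeric(table["age_in_survey_year"], errors="coerce")
        out = out.fillna(fallback)
    if "birth_date" in table and "survey_date" in table:
        need = out.isna()
        if need.any():
            birth = pd.to_datetime(table.loc[need, "birth_date"], errors="coerce")
            survey = pd.to_datetime(table.loc[need, "survey_date"], errors="coerce")
            years = survey.dt.year - birth.dt.year
            before = (
                (survey.dt.month < birth.dt.month)
                | ((survey.dt.month == birth.dt.month) & (survey.dt.day < birth.dt.day))
            )
            out.loc[need] = (years - before.astype("float")).astype(float)
    return out


# ------------------------------------------------------------------- eligibility

#: Waves with usable frailty data, per analysis. Waves 3 and 7 are dropped from
#: everything (near-total missingness of key variables); wave 5 additionally from
#: all instrument analyses (grip strength >80% missing); waves 5, 6 and 8 from
#: index *complete-case* analyses (two index items deprecated from wave 5).
_WAVES = {
    ("instrument", "multiple_imputation"): frozenset({1, 2, 4, 6, 8}),
    ("instrument", "complete_case"): frozenset({1, 2, 4, 6, 8}),
    ("index", "multiple_imputation"): frozenset({1, 2, 4, 5, 6, 8}),
    ("index", "complete_case"): frozenset({1, 2, 4}),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Which frailty method / missing-data approach a run uses, plus run knobs."""

    method: str = "instrument"
    missing_approach: str = "multiple_imputation"
    m: int = 10
    seed: int = 0
    ppp: bool = True
    included_waves: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.method not in ("instrument", "index"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.missing_approach not in ("multiple_imputation", "complete_case"):
            raise ValueError(f"unknown missing_approach {self.missing_approach!r}")
        if not self.included_waves:
            object.__setattr__(
                self, "included_waves", _WAVES[(self.method, self.missing_approach)]
            )

    @property
    def gdp_column(self) -> str:
        return "gdp_kEUR_ppp" if self.ppp else "gdp_kEUR"


def filter_eligible(table: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Apply the eligibility filters: age >= 50, allowed wave, known gender.

    Adds/refreshes the resolved ``age`` and ``age_band`` columns. Idempotent.
    Counts removed per rule are logged.
    """
    if table.empty:
        out = table.copy()
        for col in ("age", "age_band"):
            if col not in out:
                out[col] = pd.Series(dtype=float if col == "age" else object)
        return out
    out = table.copy()
    out["age"] = resolve_age_column(out)
    n0 = len(out)
    out = out[out["age"].notna() & (out["age"] >= 50)]
    n_age = n0 - len(out)
    out = out[out["wave"].astype(int).isin(config.included_waves)]
    n_wave = n0 - n_age - len(out)
    if "gender" in out:
        out = out[out["gender"].isin(GENDERS)]
    n_gender = n0 - n_age - n_wave - len(out)
    logger.info(
        "eligibility: removed %d (age unknown or <50), %d (excluded wave), "
        "%d (missing gender); %d retained",
        n_age, n_wave, n_gender, len(out),
    )
    out["age_band"] = out["age"].map(derive_age_band)
    return out


# ------------------------------------------------------- education derived vars

def carry_forward_education(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing ``education_years`` from other waves of the same subject.

    Never overwrites a non-missing value. When a subject reports distinct values
    in different waves, missing cells are filled from the most recent (highest
    wave) non-missing record.
    """
    out = table.copy()
    edu = pd.to_numeric(out["education_years"], errors="coerce")

    def _fill_value(sub: pd.DataFrame) -> float:
        known = sub.dropna(subset=["_edu"]).sort_values("wave")
        return known["_edu"].iloc[-1] if len(known) else np.nan

    out["_edu"] = edu
    fills = out.groupby("subject_id", sort=False).apply(_fill_value, include_groups=False)
    filled = edu.where(edu.notna(), out["subject_id"].map(fills))
    out["education_years"] = filled
    return out.drop(columns="_edu")


def education_quartiles(table: pd.DataFrame) -> pd.DataFrame:
    """Categorise ``education_years`` into sample quartiles (Q1..Q4).

    Cut points are linear-interpolation sample quantiles at 0.25/0.5/0.75.
    Missing values stay missing. A degenerate distribution (fewer than two
    distinct cut points) yields fewer categories with a warning.
    """
    out = table.copy()
    edu = pd.to_numeric(out["education_years"], errors="coerce")
    observed = edu.dropna()
    if len(observed) < 4:
        raise ValueError("need at least 4 observed education_years values")
    cuts = np.quantile(observed, [0.25, 0.5, 0.75])
    edges = [-np.inf, *cuts, np.inf]
    uniq_edges = sorted(set(edges))
    if len(uniq_edges) < len(edges):
        warnings.warn(
            "degenerate education distribution: fewer than 4 quartile categories",
            stacklevel=2,
        )
    labels = [f"Q{i + 1}" for i in range(len(uniq_edges) - 1)]
    out["education_quartile"] = pd.cut(edu, uniq_edges, labels=labels, right=True)
    return out


# ------------------------------------------------------------------ country data

GDP_WINDOW = tuple(range(2000, 2005))


def average_gdp(annual_values: dict[int, float], years=GDP_WINDOW) -> float:
    """Mean GDP per capita over the reference window, in thousand EUR.

    ``annual_values`` maps calendar year to GDP/capita in EUR. The mean is taken
    over whichever window years are present; a warning is raised when any is
    missing, an error when all are.
    """
    vals = [annual_values[y] for y in years if y in annual_values and annual_values[y] is not None]
    if not vals:
        raise ValueError(f"no GDP values available in window {years[0]}-{years[-1]}")
    if len(vals) < len(years):
        warnings.warn(
            f"GDP window {years[0]}-{years[-1]}: only {len(vals)}/{len(years)} years "
            "available; averaging the rest",
            stacklevel=2,
        )
    return float(np.mean(vals)) / 1000.0


def load_country_attributes(path) -> pd.DataFrame:
    """Load a country-attributes table (wide or long layout).

    Wide layout: columns ``country,name,share_participant,gdp_kEUR,gdp_kEUR_ppp``.
    Long layout: columns ``country,year,gdp_eur`` (optionally ``ppp_factor``), in
    which case 2000-2004 means are computed via :func:`average_gdp` and the PPP
    column is derived by dividing by the country's ppp_factor when given.
    """
    df = pd.read_csv(path, comment="#")
    if "gdp_kEUR" in df.columns:
        out = df.copy()
        if "share_participant" in out:
            out["share_participant"] = out["share_participant"].astype(bool)
        return out
    if not {"country", "year", "gdp_eur"} <= set(df.columns):
        raise ValueError("unrecognised country-attributes layout")
    rows = []
    for iso2, grp in df.groupby("country"):
        annual = dict(zip(grp["year"].astype(int), grp["gdp_eur"].astype(float)))
        gdp = average_gdp(annual)
        ppp = gdp
        if "ppp_factor" in grp and grp["ppp_factor"].notna().any():
            ppp = gdp / float(grp["ppp_factor"].dropna().iloc[0])
        row = {"country": iso2, "gdp_kEUR": gdp, "gdp_kEUR_ppp": ppp}
        if "name" in grp:
            row["name"] = grp["name"].iloc[0]
        if "share_participant" in grp:
            row["share_participant"] = bool(grp["share_participant"].iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)


def default_country_catalog() -> pd.DataFrame:
    """The shipped 42-country catalog (29 observed + 13 prediction-only).

    GDP values are approximate 2000-2004 public figures in thousand EUR and are
    intended for demonstration and synthetic runs; supply a prepared attributes
    file for real analyses.
    """
    with resources.files("frailty_atlas.data").joinpath("country_catalog.csv").open() as fh:
        return load_country_attributes(fh)


def country_code(name: str, catalog: pd.DataFrame | None = None) -> str:
    """Resolve a country name (or ISO code) to its ISO-3166 alpha-2 code."""
    cat = default_country_catalog() if catalog is None else catalog
    name_l = name.strip().lower()
    hit = cat[cat["country"].str.lower() == name_l]
    if hit.empty and "name" in cat:
        hit = cat[cat["name"].str.lower() == name_l]
    if hit.empty:
        raise KeyError(f"unknown country {name!r}")
    return str(hit["country"].iloc[0])


# ------------------------------------------------------------------------- I/O

def load_survey_table(path) -> pd.DataFrame:
    """Read a long-format person-wave survey table from CSV (empty cell = missing)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "country": str})
    if "wave" in df:
        df["wave"] = df["wave"].astype(int)
    return df


def write_survey_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
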