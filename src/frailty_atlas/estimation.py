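"""Prevalence estimation and the mixed logistic frailty model.

Two estimation layers live here:

* **Descriptive**: stratified prevalence with Clopper-Pearson exact binomial
  confidence intervals, averaged over multiply-imputed datasets where present.

* **Model-based**: :class:`FrailtyGLMM`, a logistic regression of the binary
  frailty state on gender x 5-year age band and on GDP/capita (thousand EUR)
  x age band, with crossed random intercepts for subject (repeated waves) and
  country. ``fit()`` returns a :class:`GLMMResults`; results from the m imputed
  datasets are combined with Rubin's rules by :func:`rubin_pool` into a
  :class:`PooledResults`. Both results objects predict stratum prevalence for
  arbitrary (age band, gender, GDP) cells — the route used to estimate frailty
  prevalence in countries without observed survey data.

Reference levels are female and the 50-54 band; GDP enters in thousand EUR.
Predictions set both random intercepts to zero (conditional / median
prediction) by default; Monte-Carlo marginalisation over the country intercept
is available behind ``marginal=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import _rbridge

__all__ = [
    "BAND_TERMS",
    "band_term",
    "ModelSpec",
    "design_matrix",
    "prediction_design",
    "exact_ci",
    "prevalence_table",
    "FrailtyGLMM",
    "GLMMResults",
    "PooledResults",
    "fit_glmm",
    "rubin_pool",
    "predict_prevalence",
]

from .data_model import AGE_BAND_LABELS

#: age-band label -> model term fragment ("55-59" -> "age_55_59", "85+" -> "age_85p")
BAND_TERMS = {
    label: "age_" + label.replace("-", "_").replace("+", "p") for label in AGE_BAND_LABELS
}


def band_term(label: str) -> str:
    try:
        return BAND_TERMS[label]
    except KeyError:
        raise KeyError(f"unknown age band {label!r}") from None


@dataclass(frozen=True)
class ModelSpec:
    """Term structure of the mixed logistic frailty model."""

    outcome: str = "frail"
    gdp_col: str = "gdp_kEUR"
    subject_col: str = "subject_id"
    country_col: str = "country"

    @property
    def terms(self) -> tuple[str, ...]:
        bands = [band_term(b) for b in AGE_BAND_LABELS[1:]]  # ref band 50-54
        return (
            "intercept",
            "male",
            *bands,
            *[f"{b}:male" for b in bands],
            "gdp",
            *[f"{b}:gdp" for b in bands],
        )


def design_matrix(table: pd.DataFrame, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Fixed-effect design matrix with one named column per model term."""
    spec = spec or ModelSpec()
    male = (table["gender"] == "male").astype(float).to_numpy()
    gdp = pd.to_numeric(table[spec.gdp_col], errors="coerce").to_numpy(dtype=float)
    X = pd.DataFrame(index=table.index)
    X["intercept"] = 1.0
    X["male"] = male
    band = table["age_band"].astype(str)
    for label in AGE_BAND_LABELS[1:]:
        X[band_term(label)] = (band == label).astype(float)
    for label in AGE_BAND_LABELS[1:]:
        X[f"{band_term(label)}:male"] = X[band_term(label)] * male
    X["gdp"] = gdp
    for label in AGE_BAND_LABELS[1:]:
        X[f"{band_term(label)}:gdp"] = X[band_term(label)] * gdp
    unknown = set(band.unique()) - set(AGE_BAND_LABELS)
    if unknown:
        raise KeyError(f"unknown age bands {sorted(unknown)}")
    return X[list(spec.terms)]


def prediction_design(cells: pd.DataFrame, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Design matrix for prediction cells (columns gender, age_band, gdp_kEUR)."""
    spec = spec or ModelSpec()
    df = cells.copy()
    if spec.gdp_col not in df and "gdp_kEUR" in df:
        df[spec.gdp_col] = df["gdp_kEUR"]
    return design_matrix(df, spec)


# ------------------------------------------------------------------ exact CIs

def exact_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a binomial proportion."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid (k={k}, n={n})")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def prevalence_table(
    tables: pd.DataFrame | Sequence[pd.DataFrame],
    strata: Sequence[str] = ("country", "age_band", "gender"),
    frail_col: str = "frail",
    level: float = 0.95,
) -> pd.DataFrame:
    """Stratified prevalence, averaged over imputed datasets, with exact CIs.

    Each input table needs the stratum columns plus a 0/1 ``frail`` column (NaN
    rows are unclassified and ignored). With m tables, prevalence is the mean
    over datasets of the per-dataset rate; the CI is computed from the averaged
    frail count (rounded half-up) and the averaged denominator. A single table
    is the m=1 case. Empty strata yield flagged rows with n=0 and NaN CIs.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    strata = list(strata)
    per = []
    for i, tab in enumerate(tables):
        sub = tab[tab[frail_col].notna()]
        g = sub.groupby(strata, observed=True)[frail_col].agg(n="count", n_frail="sum")
        g["m_index"] = i
        per.append(g.reset_index())
    allg = pd.concat(per, ignore_index=True)
    rows = []
    for key, grp in allg.groupby(strata, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        n = float(grp["n"].mean())
        n_frail = float(grp["n_frail"].mean())
        prev = float((grp["n_frail"] / grp["n"]).mean())
        n_int = _round_half_up(n)
        k_int = min(_round_half_up(n_frail), n_int)
        if n_int >= 1:
            lo, hi = exact_ci(k_int, n_int, level)
        else:
            lo = hi = float("nan")
        rows.append(
            dict(zip(strata, key))
            | {
                "n": n,
                "n_frail": n_frail,
                "prevalence": prev,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- the model

@dataclass
class GLMMResults:
    """Results of one mixed (or fixed-effects-only) logistic fit."""

    params: pd.Series
    bse: pd.Series
    vc: dict
    converged: bool
    nobs: int
    spec: ModelSpec
    backend: str

    @property
    def sigma2_subject(self) -> float:
        return float(self.vc.get("subject", 0.0))

    @property
    def sigma2_country(self) -> float:
        return float(self.vc.get("country", 0.0))

    def predict(self, cells: pd.DataFrame, **kw) -> pd.Series:
        return predict_prevalence(self, cells, **kw)

    def summary(self) -> str:
        frame = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.params / self.bse,
                "P>|z|": 2 * stats.norm.sf(np.abs(self.params / self.bse)),
            }
        )
        head = (
            f"Mixed logistic frailty model ({self.backend} backend)\n"
            f"nobs={self.nobs}  converged={self.converged}  "
            f"var(subject)={self.sigma2_subject:.4f}  var(country)={self.sigma2_country:.4f}\n"
        )
        return head + frame.to_string(float_format=lambda v: f"{v: .4f}")


class FrailtyGLMM:
    """Mixed logistic model of frailty on age band x gender and age band x GDP.

    Parameters
    ----------
    data : DataFrame with columns ``frail`` (0/1), ``gender``, ``age_band``,
        the GDP column named by the spec, ``subject_id`` and ``country``.
    spec : ModelSpec, optional.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        if "age_band" not in data.columns:
            from .data_model import derive_age_band

            for age_col in ("age", "reported_age"):
                if age_col in data.columns:
                    data = data.assign(age_band=data[age_col].map(derive_age_band))
                    break
        cols = [self.spec.outcome, "gender", "age_band", self.spec.gdp_col,
                self.spec.subject_col, self.spec.country_col]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"model data missing columns {missing}")
        data = data.dropna(subset=[self.spec.outcome])
        y = data[self.spec.outcome].astype(float)
        if y.nunique() < 2:
            raise ValueError("degenerate outcome: both frailty classes required")
        self.data = data
        self.endog = y.to_numpy()
        self.exog = design_matrix(data, self.spec)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec | None = None,
                       gdp_col: str | None = None) -> "FrailtyGLMM":
        spec = spec or ModelSpec()
        if gdp_col is not None:
            spec = replace(spec, gdp_col=gdp_col)
        return cls(data, spec)

    def fit(self, backend: str = "lme4", **kw) -> GLMMResults:
        """Fit by maximum likelihood (Laplace approximation via lme4), or a
        fixed-effects-only ordinary logistic fit with ``backend='ordinary'``."""
        if backend == "lme4":
            params, bse, vc, converged = _rbridge.fit_glmer(
                self.exog,
                self.endog,
                self.data[self.spec.subject_col],
                self.data[self.spec.country_col],
                **kw,
            )
            return GLMMResults(params, bse, vc, converged, len(self.endog), self.spec, backend)
        if backend == "ordinary":
            import statsmodels.api as sm

            res = sm.GLM(self.endog, self.exog, family=sm.families.Binomial()).fit(**kw)
            converged = bool(res.converged) and bool(np.all(np.abs(res.params) < 50))
            return GLMMResults(
                pd.Series(res.params, index=self.exog.columns),
                pd.Series(res.bse, index=self.exog.columns),
                {"subject": 0.0, "country": 0.0},
                converged,
                len(self.endog),
                self.spec,
                backend,
            )
        raise ValueError(f"unknown backend {backend!r}")


def fit_glmm(table: pd.DataFrame, spec: ModelSpec | None = None,
             backend: str = "lme4", **kw) -> GLMMResults:
    """Functional wrapper: construct :class:`FrailtyGLMM` and fit it."""
    return FrailtyGLMM(table, spec).fit(backend=backend, **kw)


# ------------------------------------------------------------------- pooling

@dataclass
class PooledResults:
    """Rubin-pooled estimates across the m per-imputation fits.

    For each term: pooled estimate Qbar (mean of the m estimates), within-
    imputation variance W (mean squared SE), between-imputation variance B
    (sample variance of estimates), total variance T = W + (1 + 1/m) B, and
    Barnard-Rubin small-sample degrees of freedom.
    """

    params: pd.Series
    bse: pd.Series
    W: pd.Series
    B: pd.Series
    T: pd.Series
    df: pd.Series
    m: int
    spec: ModelSpec
    vc: dict = field(default_factory=dict)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), df=self.df), index=self.params.index
        )

    def predict(self, cells: pd.DataFrame, **kw) -> pd.Series:
        return predict_prevalence(self, cells, **kw)

    def summary(self) -> str:
        frame = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "t": self.tvalues,
                "df": self.df,
                "P>|t|": self.pvalues,
            }
        )
        head = f"Rubin-pooled mixed logistic frailty model (m={self.m} imputations)\n"
        return head + frame.to_string(float_format=lambda v: f"{v: .4f}")


def rubin_pool(fits: Sequence[GLMMResults], n_com: int | None = None) -> PooledResults:
    """Combine m >= 2 per-imputation fits with Rubin's rules.

    ``n_com`` optionally gives the complete-data sample size used for the
    Barnard-Rubin degrees-of-freedom adjustment; without it the large-sample
    (old) degrees of freedom are used.
    """
    if len(fits) < 2:
        raise ValueError("Rubin pooling requires m >= 2 fits")
    terms = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != terms:
            raise ValueError("term sets differ across fits")
    m = len(fits)
    Q = np.column_stack([f.params.to_numpy() for f in fits])
    U = np.column_stack([f.bse.to_numpy() ** 2 for f in fits])
    qbar = Q.mean(axis=1)
    W = U.mean(axis=1)
    B = Q.var(axis=1, ddof=1)
    T = W + (1 + 1 / m) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(T > 0, (1 + 1 / m) * B / T, 0.0)
        nu_old = np.where(lam > 0, (m - 1) / lam**2, np.inf)
        if n_com is not None:
            nu_com = max(n_com - len(terms), 1)
            nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
            df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
        else:
            df = nu_old
    df = np.minimum(df, 1e8)
    vc = {
        k: float(np.mean([f.vc.get(k, 0.0) for f in fits]))
        for k in fits[0].vc
    }
    idx = pd.Index(terms)
    return PooledResults(
        params=pd.Series(qbar, index=idx),
        bse=pd.Series(np.sqrt(T), index=idx),
        W=pd.Series(W, index=idx),
        B=pd.Series(B, index=idx),
        T=pd.Series(T, index=idx),
        df=pd.Series(df, index=idx),
        m=m,
        spec=fits[0].spec,
        vc=vc,
    )


# ---------------------------------------------------------------- prediction

def predict_prevalence(
    fit,
    cells: pd.DataFrame,
    marginal: bool = False,
    sigma2_country: float | None = None,
    n_draws: int = 2000,
    seed: int | None = None,
) -> pd.Series:
    """Predicted frailty prevalence for (age band, gender, GDP) cells.

    ``fit`` may be a :class:`GLMMResults`, :class:`PooledResults`, or a plain
    term->coefficient mapping. The default is the conditional (median)
    prediction with both random intercepts at zero. With ``marginal=True`` the
    country intercept is integrated out by Monte Carlo using
    ``sigma2_country`` (default: the fit's estimate).
    """
    if isinstance(fit, (GLMMResults, PooledResults)):
        params, spec = fit.params, fit.spec
    elif isinstance(fit, Mapping):
        params, spec = pd.Series(fit, dtype=float), ModelSpec()
    else:
        raise TypeError(f"cannot predict from {type(fit)!r}")
    X = prediction_design(cells, spec)
    missing = set(X.columns) - set(params.index)
    if missing:
        raise KeyError(f"fit lacks terms {sorted(missing)}")
    eta = X.to_numpy() @ params.reindex(X.columns).to_numpy()
    if not marginal:
        return pd.Series(expit(eta), index=cells.index)
    if sigma2_country is None:
        sigma2_country = getattr(fit, "sigma2_country", None)
        if sigma2_country is None:
            sigma2_country = float(getattr(fit, "vc", {}).get("country", 0.0))
    rng = np.random.default_rng(seed)
    draws = rng.normal(0.0, np.sqrt(sigma2_country), size=n_draws)
    probs = expit(eta[:, None] + draws[None, :]).mean(axis=1)
    return pd.Series(probs, index=cells.index)
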