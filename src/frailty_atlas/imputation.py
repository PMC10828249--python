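"""Missing-data handling: complete-case filtering, chained multiple imputation,
the direct frailty-index fallback, and missingness diagnostics.

The multiple-imputation engine is a chained-equations sampler: each incomplete
column is imputed in turn conditional on current values of the others, cycling
for a fixed number of iterations, producing ``m`` completed datasets (default
10). Numeric columns use predictive mean matching (PMM: each missing entry
receives the observed value of one of the ``k`` donors with closest
regression-predicted means, so imputations always lie in the observed support);
binary columns use logistic regression with Bernoulli draws from fitted
probabilities.

Predictor sets follow the analysis design: the instrument analyses condition on
age band, gender, the five instrument components, education years,
self-perceived health and living arrangement; the index analyses on age band,
gender, the 40 index items, osteoporosis-drug exposure and the same
auxiliaries. Where item-level chains leave a record's 40-item set incomplete,
the frailty index itself is imputed directly as a single continuous variable by
PMM (:func:`direct_index_impute`).

Observed cells are never modified by any path here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "ImputationConfig",
    "CompletedDatasets",
    "complete_case_filter",
    "pmm_impute",
    "binary_impute",
    "chained_impute",
    "direct_index_impute",
    "missingness_diagnostics",
]

logger = logging.getLogger(__name__)

#: auxiliary categorical predictors encoded as dummies when present
_CATEGORICAL = ("gender", "age_band", "living_with_partner")
_AUX_NUMERIC = ("education_years", "self_perceived_health")


@dataclass(frozen=True)
class ImputationConfig:
    """Chained-equations settings (m completed datasets, PMM donor count k)."""

    m: int = 10
    iterations: int = 10
    k: int = 5
    seed: int = 0
    #: columns to impute; None = all incomplete columns outside id/demographics
    targets: Sequence[str] | None = None
    #: extra always-available predictor columns (encoded per type)
    predictors: Sequence[str] = field(
        default_factory=lambda: ("age_band", "gender", "education_years",
                                 "self_perceived_health", "living_with_partner")
    )

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.k < 1:
            raise ValueError("PMM donor count k must be >= 1")


@dataclass
class CompletedDatasets:
    """The m completed copies of a survey table plus imputation metadata."""

    datasets: list[pd.DataFrame]
    flags: pd.DataFrame  # True where the cell was originally missing
    config: ImputationConfig

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)


# ------------------------------------------------------------- complete cases

def complete_case_filter(table: pd.DataFrame, required: Sequence[str]) -> pd.DataFrame:
    """Keep rows with every required item observed (listwise deletion)."""
    required = [c for c in required if c in table.columns]
    keep = table[required].notna().all(axis=1) if required else pd.Series(True, index=table.index)
    dropped = int((~keep).sum())
    logger.info("complete-case filter: dropped %d of %d rows", dropped, len(table))
    if keep.sum() == 0 and len(table) > 0:
        warnings.warn("complete-case filter removed every row", stacklevel=2)
    return table[keep].copy()


# -------------------------------------------------------------- column models

def _design(predictors: pd.DataFrame) -> np.ndarray:
    """Numeric design with intercept; categoricals dummy-coded, NaNs mean-filled."""
    parts = [np.ones((len(predictors), 1))]
    for col in predictors.columns:
        s = predictors[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s.astype(str), drop_first=True, dtype=float)
            parts.append(dummies.to_numpy())
        else:
            v = pd.to_numeric(s, errors="coerce")
            v = v.fillna(v.mean() if v.notna().any() else 0.0)
            parts.append(v.to_numpy(dtype=float)[:, None])
    return np.hstack(parts)


def pmm_impute(
    target: pd.Series,
    predictors: pd.DataFrame,
    k: int = 5,
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    """Predictive mean matching for one numeric column.

    A linear regression of the observed target on the predictors yields
    predicted means for all rows; each missing entry receives the observed
    value of one of the ``k`` donors with closest predicted mean, drawn
    uniformly. Every imputed value is an observed donor value.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    obs = target.notna()
    if not (~obs).any():
        return target.copy()
    n_obs = int(obs.sum())
    if n_obs < k:
        raise ValueError(f"need at least k={k} observed donors, have {n_obs}")
    X = _design(predictors)
    y = target[obs].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X[obs.to_numpy()], y, rcond=None)
    pred = X @ beta
    donor_pred = pred[obs.to_numpy()]
    out = target.copy().astype(float)
    miss_idx = np.flatnonzero(~obs.to_numpy())
    for i in miss_idx:
        d = np.abs(donor_pred - pred[i])
        nearest = np.argpartition(d, k - 1)[:k]
        out.iloc[i] = y[nearest[rng.integers(k)]]
    return out


def binary_impute(
    target: pd.Series,
    predictors: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    """Logistic-regression imputation for one binary column.

    A logistic model is fitted on observed rows and missing entries are drawn
    Bernoulli from the predicted probabilities. With a single observed class
    the fill is degenerate (that class) with a warning.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    obs = target.notna()
    if not (~obs).any():
        return target.copy()
    y = target[obs].astype(float)
    out = target.copy().astype(float)
    miss_mask = ~obs
    classes = set(y.unique())
    if len(classes) < 2:
        warnings.warn(
            f"single observed class {classes}; degenerate binary fill", stacklevel=2
        )
        out[miss_mask] = next(iter(classes)) if classes else np.nan
        return out
    X = _design(predictors)
    Xo = X[obs.to_numpy()]
    beta = _logistic_fit(Xo, y.to_numpy())
    p = expit(X[miss_mask.to_numpy()] @ beta)
    out[miss_mask] = (rng.random(p.shape) < p).astype(float)
    return out


def _logistic_fit(X: np.ndarray, y: np.ndarray, l2: float = 1e-4, iters: int = 25) -> np.ndarray:
    """Ridge-stabilised Newton logistic fit (small l2 guards separation)."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = expit(X @ beta)
        W = p * (1 - p) + 1e-10
        H = X.T @ (X * W[:, None]) + l2 * np.eye(X.shape[1])
        g = X.T @ (y - p) - l2 * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


# ------------------------------------------------------------- chained engine

def _is_binary(series: pd.Series) -> bool:
    vals = set(pd.to_numeric(series.dropna(), errors="coerce").unique())
    return vals <= {0.0, 1.0}


def chained_impute(table: pd.DataFrame, config: ImputationConfig | None = None) -> CompletedDatasets:
    """Multiple imputation by chained equations.

    Produces ``config.m`` completed datasets; each chain initialises missing
    cells by random draws from the observed marginal, then cycles through
    incomplete columns (ascending missingness count) for ``config.iterations``
    sweeps, imputing numeric columns by PMM and binary columns by logistic
    regression. Deterministic given the table and ``config.seed``. A column
    with no observed values at all cannot be imputed and is left missing with
    a warning (such records trigger the direct-index fallback downstream).
    """
    config = config or ImputationConfig()
    id_like = {"subject_id", "country", "wave", "survey_year", "reported_age",
               "age", "age_band", "gender", "gdp_kEUR"}
    if config.targets is not None:
        targets = [c for c in config.targets if c in table.columns]
    else:
        targets = [
            c for c in table.columns
            if c not in id_like and table[c].isna().any()
        ]
    flags = table[targets].isna() if targets else pd.DataFrame(index=table.index)
    predictors_all = [c for c in config.predictors if c in table.columns]
    # ascending missingness visit order
    targets = sorted(targets, key=lambda c: int(table[c].isna().sum()))
    unfillable = [c for c in targets if table[c].notna().sum() == 0]
    if unfillable:
        warnings.warn(f"columns with no observed values left missing: {unfillable}",
                      stacklevel=2)
    targets = [c for c in targets if c not in unfillable]
    binary_cols = {c for c in targets if _is_binary(table[c])}

    datasets = []
    for chain in range(config.m):
        rng = np.random.default_rng((config.seed, chain))
        d = table.copy()
        for c in targets:  # marginal-draw initialisation
            miss = d[c].isna()
            donors = d.loc[~miss, c].to_numpy()
            d.loc[miss, c] = rng.choice(donors, size=int(miss.sum()))
        for _ in range(config.iterations):
            for c in targets:
                miss = flags[c]
                work = d.copy()
                work.loc[miss, c] = np.nan
                pred_cols = [p for p in predictors_all if p != c]
                pred_cols += [t for t in targets if t != c and t not in pred_cols]
                P = work[pred_cols]
                if c in binary_cols:
                    filled = binary_impute(work[c], P, rng)
                else:
                    kk = min(config.k, int((~miss).sum()))
                    filled = pmm_impute(work[c], P, k=kk, rng=rng)
                d[c] = filled
        datasets.append(d)
    return CompletedDatasets(datasets=datasets, flags=flags, config=config)


# ------------------------------------------------------- direct-index fallback

def direct_index_impute(
    table: pd.DataFrame,
    fi_col: str = "fi",
    predictors: Sequence[str] = ("age_band", "gender", "education_years",
                                 "self_perceived_health", "living_with_partner"),
    k: int = 5,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Impute the frailty index directly (PMM) where item-level chains failed.

    Rows with missing ``fi`` receive an observed record's index value via PMM
    on age band, gender, education, self-perceived health and living
    arrangement; the imputed index therefore always lies in the observed
    [0, 1] support.
    """
    out = table.copy()
    if not out[fi_col].isna().any():
        return out
    obs = out[fi_col].notna()
    if obs.sum() == 0:
        raise ValueError("no observed frailty-index donors")
    pred_cols = [c for c in predictors if c in out.columns]
    k = min(k, int(obs.sum()))
    out[fi_col] = pmm_impute(out[fi_col], out[pred_cols], k=k, rng=rng)
    return out


# ----------------------------------------------------------------- diagnostics

def _positivity(series: pd.Series, name: str) -> pd.Series:
    """Deficit-positivity of observed values (continuous: below observed median)."""
    v = pd.to_numeric(series, errors="coerce")
    if name == "self_perceived_health":
        return v >= 4
    if _is_binary(series):
        return v == 1
    return v < v.median()


def missingness_diagnostics(
    table: pd.DataFrame,
    variables: Sequence[str],
    stratum: str = "age_band",
) -> pd.DataFrame:
    """Chi-square association of data completeness with age group and positivity.

    Completeness is the all-items-observed indicator over ``variables``. One
    row tests completeness against the stratifying column; one row per
    variable tests completeness against that variable's observed
    deficit-positivity. Pearson chi-square without continuity correction.
    """
    variables = [v for v in variables if v in table.columns]
    complete = table[variables].notna().all(axis=1)
    rows = []

    def _chi(ct: pd.DataFrame, against: str):
        ct = ct.loc[:, ct.sum(axis=0) > 0]
        if ct.shape[1] < 2 or ct.shape[0] < 2:
            warnings.warn(f"degenerate contingency for {against!r}; skipped", stacklevel=3)
            return
        res = stats.chi2_contingency(ct.to_numpy(), correction=False)
        rows.append({"against": against, "chi2": float(res[0]),
                     "p_value": float(res[1]), "dof": int(res[2])})

    if stratum in table.columns:
        _chi(pd.crosstab(complete, table[stratum]), stratum)
    for v in variables:
        obs = table[v].notna()
        if obs.sum() == 0:
            warnings.warn(f"{v!r} entirely missing; positivity test skipped", stacklevel=2)
            continue
        pos = _positivity(table.loc[obs, v], v)
        _chi(pd.crosstab(complete[obs], pos), f"{v}:positive")
    return pd.DataFrame(rows)
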