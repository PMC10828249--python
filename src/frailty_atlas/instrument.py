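"""Weighted five-component frailty instrument with gender-specific thresholds.

The instrument scores grip strength (kg) plus four self-reported deficits —
fatigue, appetite loss / eating less, mobility difficulty (stairs and/or
walking 100 m), low physical activity — into a gender-specific discrete factor
score, then classifies frail/non-frail against a gender-specific threshold
(score on or beyond the threshold is frail).

Weights and thresholds are data, not code: they are loaded from a YAML weight
set which must carry a provenance note (unlabelled weight sets are refused).
The shipped default, ``instrument_weights_synthetic.yaml``, is a constructed
synthetic stand-in for the published set, which is not redistributed here. An
auxiliary unweighted mode (count of the five phenotype deficits, frail if
>= 3) is provided for weight-free use and is clearly non-canonical.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "COMPONENTS",
    "InstrumentComponents",
    "InstrumentWeightSet",
    "InstrumentResult",
    "IncompleteRecordError",
    "default_weights",
    "extract_components",
    "discrete_factor_score",
    "classify_instrument",
    "score_instrument",
    "fried_count",
    "score_instrument_table",
]

COMPONENTS = (
    "grip_strength",
    "fatigue",
    "appetite_loss",
    "mobility_difficulty",
    "low_activity",
)

#: Raw survey columns feeding each compound component (any-positive merge).
COMPONENT_SOURCES: dict[str, tuple[str, ...]] = {
    "appetite_loss": ("appetite_loss", "eating_less"),
    "mobility_difficulty": ("difficulty_climbing_stairs", "difficulty_walking_100m"),
}


class IncompleteRecordError(ValueError):
    """Raised when a component needed for scoring is missing."""


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class InstrumentComponents:
    grip_strength: float | None
    fatigue: int | None
    appetite_loss: int | None
    mobility_difficulty: int | None
    low_activity: int | None

    @property
    def complete(self) -> bool:
        return all(getattr(self, c) is not None for c in COMPONENTS)


@dataclass(frozen=True)
class InstrumentWeightSet:
    """Gender-specific intercept, component weights and frailty threshold."""

    genders: dict
    provenance: str
    fried_cutoffs: dict | None = None

    def __post_init__(self):
        if not self.provenance or not str(self.provenance).strip():
            raise ValueError("refusing weight set without a provenance note")
        for g in ("female", "male"):
            if g not in self.genders:
                raise ValueError(f"weight set missing gender {g!r}")
            spec = self.genders[g]
            for key in ("intercept", "weights", "threshold"):
                if key not in spec:
                    raise ValueError(f"{g}: weight set missing {key!r}")
            names = set(spec["weights"])
            if names != set(COMPONENTS):
                raise ValueError(
                    f"{g}: weights must cover exactly {sorted(COMPONENTS)}, got {sorted(names)}"
                )
            thr = float(spec["threshold"])
            if not thr == thr or thr in (float("inf"), float("-inf")):
                raise ValueError(f"{g}: non-finite threshold")

    @classmethod
    def from_file(cls, path) -> "InstrumentWeightSet":
        if hasattr(path, "read"):
            raw = yaml.safe_load(path)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        return cls(
            genders=raw["genders"],
            provenance=str(raw.get("provenance", "")),
            fried_cutoffs=raw.get("fried_cutoffs"),
        )


def default_weights() -> InstrumentWeightSet:
    """The shipped synthetic stand-in weight set (see module docstring)."""
    with resources.files("frailty_atlas.data").joinpath(
        "instrument_weights_synthetic.yaml"
    ).open() as fh:
        return InstrumentWeightSet.from_file(fh)


# ----------------------------------------------------------------- components

def _any_positive(values) -> int | None:
    if any(not _is_missing(v) and int(v) == 1 for v in values):
        return 1
    if all(not _is_missing(v) and int(v) == 0 for v in values):
        return 0
    return None


def extract_components(record: Mapping) -> InstrumentComponents:
    """Map raw survey columns onto the five instrument components.

    Grip strength is the maximum over the available hand measurements
    (``grip_strength`` and/or ``grip_left``/``grip_right``). Compound components
    are positive if any sub-item is positive and missing only when no positive
    sub-item exists and at least one sub-item is missing.
    """
    grips = [
        record.get(c)
        for c in ("grip_strength", "grip_left", "grip_right")
        if not _is_missing(record.get(c))
    ]
    grip = max(float(g) for g in grips) if grips else None

    def simple(col):
        v = record.get(col)
        return None if _is_missing(v) else int(v)

    return InstrumentComponents(
        grip_strength=grip,
        fatigue=simple("fatigue"),
        appetite_loss=_any_positive([record.get(c) for c in COMPONENT_SOURCES["appetite_loss"]]),
        mobility_difficulty=_any_positive(
            [record.get(c) for c in COMPONENT_SOURCES["mobility_difficulty"]]
        ),
        low_activity=simple("low_activity"),
    )


# -------------------------------------------------------------------- scoring

def _grip_term(weight_spec, grip: float) -> float:
    if isinstance(weight_spec, Mapping):  # categorised grip term
        for cat in weight_spec["categories"]:
            upper = cat.get("upper")
            if upper is None or grip < float(upper):
                return float(cat["value"])
        raise ValueError("grip categories do not cover the value range")
    return float(weight_spec) * grip


def discrete_factor_score(
    components: InstrumentComponents, gender: str, weights: InstrumentWeightSet
) -> float:
    """Gender-specific linear factor score; higher is more frail."""
    if gender not in ("female", "male"):
        raise ValueError(f"unknown gender {gender!r}")
    if not components.complete:
        missing = [c for c in COMPONENTS if getattr(components, c) is None]
        raise IncompleteRecordError(f"missing components: {missing}")
    spec = weights.genders[gender]
    w = spec["weights"]
    score = float(spec["intercept"])
    score += _grip_term(w["grip_strength"], components.grip_strength)
    for comp in COMPONENTS[1:]:
        score += float(w[comp]) * getattr(components, comp)
    return score


def classify_instrument(score: float, gender: str, weights: InstrumentWeightSet) -> str:
    """Frail iff the factor score reaches the gender-specific threshold."""
    if gender not in ("female", "male"):
        raise ValueError(f"unknown gender {gender!r}")
    if not score == score:
        raise ValueError("score is not finite")
    thr = float(weights.genders[gender]["threshold"])
    return "frail" if score >= thr else "non_frail"


@dataclass(frozen=True)
class InstrumentResult:
    factor_score: float | None
    classification: str | None
    complete: bool


def score_instrument(
    record: Mapping, weights: InstrumentWeightSet | None = None
) -> InstrumentResult:
    """Extract, score and classify one record; incomplete records are flagged."""
    weights = weights or default_weights()
    comps = extract_components(record)
    if not comps.complete:
        return InstrumentResult(None, None, False)
    gender = record["gender"]
    score = discrete_factor_score(comps, gender, weights)
    return InstrumentResult(score, classify_instrument(score, gender, weights), True)


def fried_count(
    components: InstrumentComponents, gender: str, weights: InstrumentWeightSet | None = None
) -> int:
    """Unweighted phenotype deficit count (non-canonical auxiliary mode).

    Grip strength counts as the weakness deficit when below the gender cutoff;
    frailty under this mode is a count >= 3 of the five deficits.
    """
    weights = weights or default_weights()
    if not components.complete:
        raise IncompleteRecordError("all five components required")
    cutoffs = weights.fried_cutoffs or {"female": 20.0, "male": 32.0}
    n = int(components.grip_strength < float(cutoffs[gender]))
    n += sum(int(getattr(components, c)) for c in COMPONENTS[1:])
    return n


def score_instrument_table(
    table: pd.DataFrame, weights: InstrumentWeightSet | None = None
) -> pd.DataFrame:
    """Row-wise instrument scoring; adds ``factor_score``, ``frail``, ``fi_complete``-style flags."""
    weights = weights or default_weights()
    out = table.copy()
    scores, frails, completes = [], [], []
    for rec in out.to_dict("records"):
        res = score_instrument(rec, weights)
        scores.append(res.factor_score if res.factor_score is not None else float("nan"))
        frails.append(float(res.classification == "frail") if res.complete else float("nan"))
        completes.append(res.complete)
    out["factor_score"] = scores
    out["frail"] = frails
    out["instrument_complete"] = completes
    return out
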