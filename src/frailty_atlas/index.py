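"""Deficit-accumulation frailty index over a 40-item catalog.

Each catalog item is scored into ``[0, 1]`` (0 = deficit absent, 1 = fully
present); the frailty index (FI) is the arithmetic mean of the 40 item scores
and a subject is classified frail when FI >= 0.25.

Completeness is strict: the FI is computed only when *all* 40 items can be
scored. Records with any unscored item are routed to imputation or dropped in
complete-case analyses; the common alternative of shrinking the denominator to
the observed items is deliberately not used, because missing items are handled
by imputation or listwise deletion here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "FRAILTY_INDEX_THRESHOLD",
    "DeficitDefinition",
    "DeficitCatalog",
    "FrailtyIndexResult",
    "default_catalog",
    "score_self_perceived_health",
    "merge_arthritis",
    "score_deficit",
    "compute_index",
    "classify_index",
    "score_index_table",
]

FRAILTY_INDEX_THRESHOLD = 0.25

DEFAULT_WAVES = frozenset({1, 2, 4, 5, 6, 8})

_GROUPS = {"ADL": 16, "chronic_disease": 10, "other": 14}


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class DeficitDefinition:
    """One catalog item: how a raw survey value maps to a deficit score."""

    name: str
    group: str
    value_type: str  # binary | ordinal5 | composite_any
    components: tuple[str, ...] = ()
    waves: frozenset[int] = DEFAULT_WAVES
    synthetic: bool = False

    def columns(self) -> tuple[str, ...]:
        """Raw survey columns this item reads."""
        return self.components if self.value_type == "composite_any" else (self.name,)


@dataclass(frozen=True)
class DeficitCatalog:
    items: tuple[DeficitDefinition, ...]
    provenance: str = ""

    def __post_init__(self):
        if len(self.items) != 40:
            raise ValueError(f"catalog must have exactly 40 items, got {len(self.items)}")
        counts: dict[str, int] = {}
        for it in self.items:
            counts[it.group] = counts.get(it.group, 0) + 1
            if it.value_type not in ("binary", "ordinal5", "composite_any"):
                raise ValueError(f"{it.name}: unknown value_type {it.value_type!r}")
            if it.value_type == "composite_any" and not it.components:
                raise ValueError(f"{it.name}: composite_any item needs components")
        if counts != _GROUPS:
            raise ValueError(f"group sizes must be {_GROUPS}, got {counts}")

    def available_items(self, wave: int | None) -> tuple[DeficitDefinition, ...]:
        if wave is None:
            return self.items
        return tuple(it for it in self.items if wave in it.waves)

    def item(self, name: str) -> DeficitDefinition:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    def raw_columns(self) -> list[str]:
        cols: list[str] = []
        for it in self.items:
            cols.extend(it.columns())
        return cols

    @classmethod
    def from_file(cls, path) -> "DeficitCatalog":
        if hasattr(path, "read"):
            raw = yaml.safe_load(path)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        items = []
        for spec in raw["items"]:
            items.append(
                DeficitDefinition(
                    name=spec["name"],
                    group=spec["group"],
                    value_type=spec["value_type"],
                    components=tuple(spec.get("components", ())),
                    waves=frozenset(spec.get("waves", DEFAULT_WAVES)),
                    synthetic=bool(spec.get("synthetic", False)),
                )
            )
        return cls(items=tuple(items), provenance=str(raw.get("provenance", "")))


def default_catalog() -> DeficitCatalog:
    """The shipped default catalog (printed structure; placeholder item names)."""
    with resources.files("frailty_atlas.data").joinpath("deficit_catalog.yaml").open() as fh:
        return DeficitCatalog.from_file(fh)


# ------------------------------------------------------------------- scoring

def score_self_perceived_health(level: int) -> float:
    """Equal-step ordinal scoring of the 5-level self-perceived-health item.

    Level 1 (best) scores 0, level 5 (worst) scores 1, intermediate levels
    0.25 / 0.5 / 0.75.
    """
    level = int(level)
    if not 1 <= level <= 5:
        raise ValueError(f"self-perceived-health level must be 1..5, got {level}")
    return (level - 1) * 0.25


def merge_arthritis(ra, oa):
    """Any-positive merge of the two dichotomised arthritis items.

    Positive if either is positive; negative only when both are observed
    negative; missing otherwise.
    """
    vals = [ra, oa]
    if any(not _is_missing(v) and int(v) == 1 for v in vals):
        return 1
    if all(not _is_missing(v) and int(v) == 0 for v in vals):
        return 0
    return None


def _any_positive(values: Sequence) -> Any:
    if any(not _is_missing(v) and int(v) == 1 for v in values):
        return 1
    if all(not _is_missing(v) and int(v) == 0 for v in values):
        return 0
    return None


def score_deficit(definition: DeficitDefinition, raw) -> float | None:
    """Score one raw value (or component tuple) into [0, 1]; missing propagates."""
    if definition.value_type == "composite_any":
        if not isinstance(raw, (tuple, list)):
            raise TypeError(f"{definition.name}: composite item expects a sequence of values")
        merged = _any_positive(raw)
        return None if merged is None else float(merged)
    if _is_missing(raw):
        return None
    if definition.value_type == "binary":
        v = float(raw)
        if v not in (0.0, 1.0):
            raise TypeError(f"{definition.name}: binary item got {raw!r}")
        return v
    if definition.value_type == "ordinal5":
        return score_self_perceived_health(int(raw))
    raise AssertionError(definition.value_type)


@dataclass(frozen=True)
class FrailtyIndexResult:
    fi: float | None
    n_items_scored: int
    complete: bool
    classification: str | None

    def __post_init__(self):
        if self.fi is not None and not 0.0 <= self.fi <= 1.0:
            raise ValueError(f"frailty index {self.fi} outside [0, 1]")


def classify_index(fi: float) -> str:
    """Frail iff FI >= 0.25 (boundary counts as frail)."""
    if not 0.0 <= fi <= 1.0:
        raise ValueError(f"frailty index {fi} outside [0, 1]")
    return "frail" if fi >= FRAILTY_INDEX_THRESHOLD else "non_frail"


def compute_index(
    record: Mapping[str, Any],
    catalog: DeficitCatalog | None = None,
    wave: int | None = None,
) -> FrailtyIndexResult:
    """Score all 40 catalog items of one record and average them.

    ``record`` maps raw survey column names to values. When ``wave`` is given,
    items unavailable in that wave are treated as unscorable, so records from
    waves with deprecated items can never be complete. The FI is reported only
    for complete records.
    """
    catalog = catalog or default_catalog()
    available = {it.name for it in catalog.available_items(wave)}
    scores: list[float] = []
    n_scored = 0
    complete = True
    for item in catalog.items:
        if item.name not in available:
            complete = False
            continue
        if item.value_type == "composite_any":
            raw = tuple(record.get(c) for c in item.components)
        else:
            raw = record.get(item.name)
        s = score_deficit(item, raw)
        if s is None:
            complete = False
        else:
            n_scored += 1
            scores.append(s)
    if not complete:
        return FrailtyIndexResult(None, n_scored, False, None)
    fi = math.fsum(scores) / len(catalog.items)
    return FrailtyIndexResult(fi, n_scored, True, classify_index(fi))


def score_index_table(
    table: pd.DataFrame,
    catalog: DeficitCatalog | None = None,
    use_wave: bool = True,
) -> pd.DataFrame:
    """Apply :func:`compute_index` row-wise; adds ``fi``, ``frail``, ``fi_complete``.

    ``frail`` is 1/0 for complete records and NaN otherwise.
    """
    catalog = catalog or default_catalog()
    out = table.copy()
    fis, frails, completes = [], [], []
    records = out.to_dict("records")
    for rec in records:
        wave = int(rec["wave"]) if use_wave and "wave" in rec and not _is_missing(rec["wave"]) else None
        res = compute_index(rec, catalog, wave=wave)
        fis.append(res.fi if res.fi is not None else float("nan"))
        frails.append(
            float(res.classification == "frail") if res.complete else float("nan")
        )
        completes.append(res.complete)
    out["fi"] = fis
    out["frail"] = frails
    out["fi_complete"] = completes
    return out
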