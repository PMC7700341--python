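"""Instrument representation and scoring.

The instrument is a pool of picture-based parent-report items, each coded on a
five-point scale with the highest score indicating the healthier behavior.
Option scores live on a half-point grid in [1, 5], which is why observed totals
can be non-integer (e.g. a minimum observed total of 51.5 over 18 items).
Totals over a selected item subset are dichotomized into low/high behavior
groups at a configurable threshold (default 75.0, so 74.9 is low and 75.0 is
high).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SCORE_GRID",
    "SchemaError",
    "ItemDef",
    "Codebook",
    "InstrumentResponse",
    "TotalScore",
    "ScoreGroup",
    "load_codebook",
    "score_total",
    "score_table",
    "assign_group",
]

#: resolution of the item-score grid
SCORE_GRID = 0.5


class SchemaError(ValueError):
    """Raised when a codebook or response violates the documented schema."""


def _on_grid(score: float, grid: float = SCORE_GRID) -> bool:
    return abs(score / grid - round(score / grid)) < 1e-9


@dataclass(frozen=True)
class ItemDef:
    """One instrument item: id, behavioral construct, prompt and option scores.

    ``option_scores`` maps option labels (in healthfulness order) to scores on
    the half-point grid in [1, 5]; scores must be non-decreasing in that order.
    """

    id: str
    construct: str
    prompt: str
    option_scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.option_scores) < 2:
            raise SchemaError(f"item {self.id!r}: needs >= 2 response options")
        scores = list(self.option_scores.values())
        for s in scores:
            if not (1.0 <= s <= 5.0):
                raise SchemaError(f"item {self.id!r}: score {s} outside [1, 5]")
            if not _on_grid(s):
                raise SchemaError(f"item {self.id!r}: score {s} off the {SCORE_GRID} grid")
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise SchemaError(f"item {self.id!r}: scores must be non-decreasing")


@dataclass(frozen=True)
class Codebook:
    items: tuple[ItemDef, ...]
    version_tag: str = ""

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate item ids: {sorted(dupes)}")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.id for it in self.items)

    def __getitem__(self, item_id: str) -> ItemDef:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def __len__(self) -> int:
        return len(self.items)

    def construct_of(self, item_id: str) -> str:
        return self[item_id].construct


@dataclass(frozen=True)
class InstrumentResponse:
    """Per-dyad item responses as already-coded scores (missing = absent/None)."""

    dyad_id: str
    item_scores: Mapping[str, float | None]

    def __post_init__(self) -> None:
        for item_id, s in self.item_scores.items():
            if s is None:
                continue
            if not (1.0 <= s <= 5.0) or not _on_grid(s):
                raise SchemaError(
                    f"dyad {self.dyad_id!r}, item {item_id!r}: "
                    f"score {s} not on the {SCORE_GRID} grid in [1, 5]"
                )


@dataclass(frozen=True)
class TotalScore:
    dyad_id: str
    total: float
    n_items: int
    complete: bool


@dataclass(frozen=True)
class ScoreGroup:
    dyad_id: str
    group: str  # "low" | "high"
    threshold: float


def load_codebook(path: str) -> Codebook:
    """Load and validate a JSON codebook.

    Schema::

        {"version_tag": "...",
         "items": [{"id": ..., "construct": ..., "prompt": ...,
                    "option_scores": {"label": score, ...}}, ...]}
    """
    with open(path) as fh:
        raw = json.load(fh)
    try:
        items = tuple(
            ItemDef(
                id=str(it["id"]),
                construct=str(it.get("construct", "")),
                prompt=str(it.get("prompt", "")),
                option_scores={str(k): float(v) for k, v in it["option_scores"].items()},
            )
            for it in raw["items"]
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed codebook: {exc}") from exc
    return Codebook(items=items, version_tag=str(raw.get("version_tag", "")))


def score_total(
    response: InstrumentResponse,
    codebook: Codebook,
    item_subset: Sequence[str],
) -> TotalScore:
    """Sum present item scores over ``item_subset``.

    ``complete`` is True only when every subset item is present; incomplete
    totals are partial sums and are rejected by :func:`assign_group`.
    """
    known = set(codebook.item_ids)
    unknown = [i for i in item_subset if i not in known]
    if unknown:
        raise KeyError(f"unknown item ids in subset: {unknown}")
    present = [
        response.item_scores[i]
        for i in item_subset
        if response.item_scores.get(i) is not None
    ]
    return TotalScore(
        dyad_id=response.dyad_id,
        total=float(sum(present)),
        n_items=len(item_subset),
        complete=len(present) == len(item_subset),
    )


def score_table(
    responses: pd.DataFrame,
    codebook: Codebook,
    item_subset: Sequence[str],
    id_col: str = "dyad_id",
) -> pd.DataFrame:
    """Vectorized totals for a response table (one row per dyad, one column
    per item id; missing = NaN). Returns columns dyad_id, total, n_items,
    complete."""
    known = set(codebook.item_ids)
    unknown = [i for i in item_subset if i not in known]
    if unknown:
        raise KeyError(f"unknown item ids in subset: {unknown}")
    sub = responses[list(item_subset)]
    out = pd.DataFrame(
        {
            id_col: responses[id_col].to_numpy(),
            "total": sub.sum(axis=1, skipna=True).to_numpy(),
            "n_items": len(item_subset),
            "complete": sub.notna().all(axis=1).to_numpy(),
        }
    )
    return out


def assign_group(total: TotalScore, threshold: float = 75.0) -> ScoreGroup:
    """Dichotomize a complete total: high iff total >= threshold, else low."""
    if not total.complete:
        raise ValueError(
            f"dyad {total.dyad_id!r}: incomplete totals are excluded from "
            "group assignment (complete-case policy)"
        )
    group = "high" if total.total >= threshold else "low"
    return ScoreGroup(dyad_id=total.dyad_id, group=group, threshold=threshold)
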