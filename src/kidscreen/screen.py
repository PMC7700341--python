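"""Anthropometry-driven item reduction.

Each candidate item is screened against central-adiposity markers
(BMI-for-age percentile, BMI z-score, waist-to-height ratio): an item is kept
when a higher item score goes with a lower marker. The published procedure
judged this from per-category boxplots; here the judgement is operationalized
as a rank test — the item is kept when, for at least one marker, the Spearman
correlation between item score and marker satisfies rho <= -rho_min AND the
one-sided (negative) p-value is <= alpha. Being rank-based, decisions are
invariant to any strictly increasing transform of the marker. Boxplot
rendering is provided for visual parity but never drives decisions.

The kept items are pruned, strongest (most negative) rho first with
lexicographic item-id tie-breaks, down to a target instrument size
(default 16-20 items), optionally capped per behavioral construct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .instrument import Codebook

__all__ = [
    "MARKERS",
    "ItemScreenResult",
    "ReducedInstrument",
    "discretize_item",
    "screen_item",
    "screen_pool",
    "reduce_pool",
    "item_boxplot",
]

#: marker columns looked up in the derived-anthropometry table
MARKERS = ("bmi_percentile", "bmi_z", "whtr")


@dataclass(frozen=True)
class ItemScreenResult:
    item_id: str
    construct: str
    rho: dict[str, float]  # marker -> Spearman rho
    p_one_sided: dict[str, float]  # marker -> one-sided (negative) p
    kept: bool
    reason: str = ""

    @property
    def best_rho(self) -> float:
        vals = [v for v in self.rho.values() if np.isfinite(v)]
        return min(vals) if vals else np.nan


@dataclass(frozen=True)
class ReducedInstrument:
    items: tuple[str, ...]
    per_construct: dict[str, int]
    size_range: tuple[int, int]
    under_minimum: bool = False


def discretize_item(scores: Sequence[float], min_count: int = 5) -> np.ndarray:
    """Map item scores to ordinal category codes, merging sparse levels.

    Categories start as the distinct observed score levels in ascending
    order; any level observed fewer than ``min_count`` times is merged into
    its nearest neighboring level (ties toward the lower level) until all
    categories meet the minimum or one category remains.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("no scores to discretize")
    levels = list(np.unique(x))
    # level value -> representative value after merges
    groups: list[list[float]] = [[lv] for lv in levels]

    def counts() -> list[int]:
        return [int(np.isin(x, g).sum()) for g in groups]

    while len(groups) > 1:
        c = counts()
        small = [i for i, n in enumerate(c) if n < min_count]
        if not small:
            break
        i = small[0]
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            # merge toward the nearer neighbor by level distance, lower on ties
            d_lo = groups[i][0] - groups[i - 1][-1]
            d_hi = groups[i + 1][0] - groups[i][-1]
            j = i - 1 if d_lo <= d_hi else i + 1
        lo, hi = sorted((i, j))
        groups[lo] = groups[lo] + groups[hi]
        del groups[hi]
    codes = np.empty(x.shape, dtype=int)
    for code, g in enumerate(groups):
        codes[np.isin(x, g)] = code
    return codes


def _spearman_neg(item: np.ndarray, marker: np.ndarray) -> tuple[float, float]:
    """Spearman rho and one-sided p for the negative direction."""
    res = sps.spearmanr(item, marker, alternative="less")
    return float(res.statistic), float(res.pvalue)


def screen_item(
    item_scores: Sequence[float],
    markers: pd.DataFrame,
    item_id: str = "",
    construct: str = "",
    rho_min: float = 0.05,
    alpha: float = 0.05,
    min_pairs: int = 20,
    min_count: int = 5,
) -> ItemScreenResult:
    """Screen one item against the anthropometric markers.

    Kept iff for >= 1 marker the item-marker Spearman correlation is at most
    -rho_min with one-sided p <= alpha (healthful-inverse direction).
    """
    x = np.asarray(item_scores, dtype=float)
    rho: dict[str, float] = {}
    pval: dict[str, float] = {}
    kept = False
    reason = ""
    marker_cols = [m for m in MARKERS if m in markers.columns]
    for m in marker_cols:
        y = markers[m].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs:
            rho[m], pval[m] = np.nan, np.nan
            continue
        cats = discretize_item(x[ok], min_count=min_count)
        if len(np.unique(cats)) < 2:
            rho[m], pval[m] = np.nan, np.nan
            continue
        rho[m], pval[m] = _spearman_neg(x[ok], y[ok])
        if rho[m] <= -rho_min and pval[m] <= alpha:
            kept = True
    if all(np.isnan(v) for v in rho.values()):
        reason = "insufficient pairs or degenerate item"
    elif not kept:
        reason = "no marker met the inverse-association rule"
    return ItemScreenResult(
        item_id=item_id, construct=construct, rho=rho, p_one_sided=pval, kept=kept, reason=reason
    )


def screen_pool(
    responses: pd.DataFrame,
    markers: pd.DataFrame,
    codebook: Codebook,
    rho_min: float = 0.05,
    alpha: float = 0.05,
    min_pairs: int = 20,
    min_count: int = 5,
    id_col: str = "dyad_id",
) -> list[ItemScreenResult]:
    """Screen every codebook item; tables are joined on ``dyad_id``."""
    merged = responses.merge(markers, on=id_col, how="inner", suffixes=("", "_marker"))
    results = []
    for item in codebook.items:
        if item.id not in merged.columns:
            results.append(
                ItemScreenResult(item.id, item.construct, {}, {}, False, "item not in responses")
            )
            continue
        results.append(
            screen_item(
                merged[item.id].to_numpy(dtype=float),
                merged,
                item_id=item.id,
                construct=item.construct,
                rho_min=rho_min,
                alpha=alpha,
                min_pairs=min_pairs,
                min_count=min_count,
            )
        )
    return results


def reduce_pool(
    results: Sequence[ItemScreenResult],
    size_range: tuple[int, int] = (16, 20),
    per_construct_cap: int | None = None,
) -> ReducedInstrument:
    """Select the reduced instrument from screen results.

    Keeps every passing item; if above the size maximum (or a per-construct
    cap), items with the strongest negative rho are retained, ties broken by
    item id. Fewer passing items than the minimum are all kept with an
    ``under_minimum`` warning flag.
    """
    lo, hi = size_range
    passing = [r for r in results if r.kept]
    ranked = sorted(passing, key=lambda r: (r.best_rho, r.item_id))
    selected: list[ItemScreenResult] = []
    per_construct: dict[str, int] = {}
    for r in ranked:
        if per_construct_cap is not None and per_construct.get(r.construct, 0) >= per_construct_cap:
            continue
        selected.append(r)
        per_construct[r.construct] = per_construct.get(r.construct, 0) + 1
    if len(selected) > hi:
        selected = selected[:hi]
        per_construct = {}
        for r in selected:
            per_construct[r.construct] = per_construct.get(r.construct, 0) + 1
    items = tuple(sorted(r.item_id for r in selected))
    return ReducedInstrument(
        items=items,
        per_construct=per_construct,
        size_range=(lo, hi),
        under_minimum=len(items) < lo,
    )


def item_boxplot(item_scores, marker_values, min_count: int = 5, ax=None, label: str = ""):
    """Boxplot of a marker across item-score categories (whiskers at
    1.5 * IQR) — the visual companion to the rank rule, never used for
    decisions."""
    import matplotlib.pyplot as plt

    x = np.asarray(item_scores, dtype=float)
    y = np.asarray(marker_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    cats = discretize_item(x[ok], min_count=min_count)
    data = [y[ok][cats == c] for c in np.unique(cats)]
    if ax is None:
        _, ax = plt.subplots()
    ax.boxplot(data, whis=1.5)
    ax.set_xlabel(f"{label} score category")
    ax.set_ylabel("marker")
    return ax
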