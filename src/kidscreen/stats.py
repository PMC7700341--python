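"""Nonparametric criterion-validity statistics.

Outcomes (BMI-for-age percentile, BMI z-score, waist-to-height ratio and the
three composite biomarker indices) are compared between the low- and
high-scoring instrument groups with the Kruskal-Wallis rank test (midranks,
standard tie correction, chi-square reference with k-1 df; with two groups it
is the Wilcoxon rank-sum test). Group descriptives are medians with
quartiles by linear interpolation, matching the lab module's convention.
Attrition is checked variable-by-variable: Pearson chi-square for
categoricals, Welch two-sample t for continuous variables, flagged at
alpha = 0.05. Tests are two-sided throughout and no multiplicity adjustment
is applied (per-outcome reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import indices as idx
from . import lab
from .anthropometry import LmsReference, derive_anthro
from .instrument import Codebook, score_table

__all__ = [
    "kruskal_wallis",
    "describe",
    "DescriptiveStats",
    "anova_crosscheck",
    "attrition_tests",
    "AssociationResult",
    "ValidationReport",
    "run_validation",
    "ANTHRO_OUTCOMES",
]

ANTHRO_OUTCOMES = ("bmi_percentile", "bmi_z", "whtr")


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis H and p over k >= 2 groups.

    Midranks with the standard tie correction; p from chi-square with k-1 df.
    All values identical is the exchangeable degenerate case: (H, p) = (0, 1).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrs)
    return float(h), float(p)


@dataclass(frozen=True)
class DescriptiveStats:
    median: float
    q1: float
    q3: float
    iqr: float


def describe(values: Sequence[float]) -> DescriptiveStats:
    """Median and quartiles (linear interpolation); IQR = Q3 - Q1."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no values to describe")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return DescriptiveStats(float(med), float(q1), float(q3), float(q3 - q1))


def anova_crosscheck(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA (F, p) — an optional parametric parallel to the rank
    test, never a decision rule."""
    f, p = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def attrition_tests(
    retained: pd.DataFrame,
    dropped: pd.DataFrame,
    variable_types: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare retained vs dropped samples variable-by-variable.

    ``variable_types`` maps column -> "categorical" | "continuous".
    Categorical: Pearson chi-square on the level x retention contingency;
    continuous: Welch two-sample t. Variables with a single observed level
    (or without variation) are skipped with a reason. Returns one row per
    variable: test, statistic, p, flagged, note.
    """
    rows = []
    for var, kind in variable_types.items():
        rec: dict[str, object] = {"variable": var, "type": kind, "flagged": False, "note": ""}
        a = retained[var].dropna()
        b = dropped[var].dropna()
        if kind == "categorical":
            levels = sorted(set(a.unique()) | set(b.unique()))
            if len(levels) < 2:
                rec.update(test="chi2", statistic=np.nan, p=np.nan, note="single observed level")
                rows.append(rec)
                continue
            table = np.array(
                [[int((a == lv).sum()) for lv in levels], [int((b == lv).sum()) for lv in levels]]
            )
            chi2, p, _, _ = sps.chi2_contingency(table)
            rec.update(test="chi2", statistic=float(chi2), p=float(p))
        elif kind == "continuous":
            if len(a) < 2 or len(b) < 2 or (a.std(ddof=1) == 0 and b.std(ddof=1) == 0):
                rec.update(test="t_welch", statistic=np.nan, p=np.nan, note="no variation")
                rows.append(rec)
                continue
            t, p = sps.ttest_ind(a, b, equal_var=False)
            rec.update(test="t_welch", statistic=float(t), p=float(p))
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
        rec["flagged"] = bool(np.isfinite(rec["p"]) and rec["p"] <= alpha)
        rows.append(rec)
    return pd.DataFrame(rows, columns=["variable", "type", "test", "statistic", "p", "flagged", "note"])


@dataclass(frozen=True)
class AssociationResult:
    outcome: str
    n_low: int
    n_high: int
    low: DescriptiveStats | None
    high: DescriptiveStats | None
    H: float
    p: float
    alpha: float = 0.05
    tested: bool = True
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.tested and self.p <= self.alpha


@dataclass(frozen=True)
class ValidationReport:
    results: tuple[AssociationResult, ...]
    threshold: float
    n_scored: int
    n_low: int
    n_high: int
    scaling: str

    def __getitem__(self, outcome: str) -> AssociationResult:
        for r in self.results:
            if r.outcome == outcome:
                return r
        raise KeyError(outcome)

    def to_frame(self) -> pd.DataFrame:
        """Two-group descriptive table: one row per outcome with per-group
        n/median/IQR/Q1/Q3 and the rank-test p."""
        rows = []
        for r in self.results:
            rows.append(
                {
                    "outcome": r.outcome,
                    "n_low": r.n_low,
                    "median_low": r.low.median if r.low else np.nan,
                    "iqr_low": r.low.iqr if r.low else np.nan,
                    "q1_low": r.low.q1 if r.low else np.nan,
                    "q3_low": r.low.q3 if r.low else np.nan,
                    "n_high": r.n_high,
                    "median_high": r.high.median if r.high else np.nan,
                    "iqr_high": r.high.iqr if r.high else np.nan,
                    "q1_high": r.high.q1 if r.high else np.nan,
                    "q3_high": r.high.q3 if r.high else np.nan,
                    "H": r.H,
                    "p": r.p,
                    "tested": r.tested,
                }
            )
        return pd.DataFrame(rows)


def _grouped_result(outcome: str, low: np.ndarray, high: np.ndarray, alpha: float) -> AssociationResult:
    low = low[np.isfinite(low)]
    high = high[np.isfinite(high)]
    if low.size < 2 or high.size < 2:
        return AssociationResult(
            outcome=outcome,
            n_low=int(low.size),
            n_high=int(high.size),
            low=describe(low) if low.size else None,
            high=describe(high) if high.size else None,
            H=np.nan,
            p=np.nan,
            alpha=alpha,
            tested=False,
            note="a group has < 2 members",
        )
    h, p = kruskal_wallis(low, high)
    return AssociationResult(
        outcome=outcome,
        n_low=int(low.size),
        n_high=int(high.size),
        low=describe(low),
        high=describe(high),
        H=h,
        p=p,
        alpha=alpha,
    )


def run_validation(
    responses: pd.DataFrame,
    anthro: pd.DataFrame,
    replicates: pd.DataFrame,
    controls: pd.DataFrame,
    codebook: Codebook,
    selected_items: Sequence[str],
    lms: LmsReference | None = None,
    index_specs: Sequence[idx.IndexSpec] = idx.DEFAULT_INDEX_SPECS,
    threshold: float = 75.0,
    scaling: str = "zsum",
    cv_thresholds: Mapping[str, float] | None = None,
    alpha: float = 0.05,
) -> ValidationReport:
    """End-to-end criterion validation on the raw tables.

    Scores the selected items (complete responses only), dichotomizes at the
    threshold, derives anthropometry and the QC'd biomarker panel with its
    composite indices, and tests every outcome between the two groups with
    the Kruskal-Wallis test, complete-case per outcome. Outcomes for which a
    group has fewer than 2 members are reported untested.
    """
    totals = score_table(responses, codebook, selected_items)
    totals = totals[totals["complete"]].copy()
    totals["group"] = np.where(totals["total"] >= threshold, "high", "low")
    groups = totals[["dyad_id", "total", "group"]]

    derived_anthro = derive_anthro(anthro, lms=lms)

    outcome_tables = [derived_anthro[["dyad_id", *ANTHRO_OUTCOMES]]]
    index_names: list[str] = []
    if replicates is not None and len(replicates):
        panel = lab.process_replicates(replicates, controls, cv_thresholds=cv_thresholds)
        panel = lab.derive_panel_table(panel)
        index_table = idx.build_all_indices(panel, specs=index_specs, scaling=scaling)
        index_names = [s.name for s in index_specs]
        outcome_tables.append(index_table)

    results = []
    for table in outcome_tables:
        merged = groups.merge(table, on="dyad_id", how="inner")
        for outcome in [c for c in table.columns if c != "dyad_id"]:
            low = merged.loc[merged["group"] == "low", outcome].to_numpy(dtype=float)
            high = merged.loc[merged["group"] == "high", outcome].to_numpy(dtype=float)
            results.append(_grouped_result(outcome, low, high, alpha))

    return ValidationReport(
        results=tuple(results),
        threshold=threshold,
        n_scored=int(len(groups)),
        n_low=int((groups["group"] == "low").sum()),
        n_high=int((groups["group"] == "high").sum()),
        scaling=scaling,
    )
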