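"""Laboratory QC and derived blood biomarkers.

Assay QC follows the immunoassay workflow: analytes run in triplicate
(duplicate for IGFBP-1); when the replicate coefficient of variation (CV,
sample SD / mean) is at or above the threshold, the best two of three (the
pair with minimal CV) are kept; pairs still failing are retained but flagged.
Plate-to-plate variability is adjusted multiplicatively with each plate's
internal control against the geometric mean of all plate controls. Outliers
are defined by Tukey fences: below Q1 - 1.5*IQR or above Q3 + 1.5*IQR, with
quartiles by linear interpolation between order statistics; outliers are
flagged, never removed.

Derived biomarkers: Friedewald LDL-C = TC - HDL-C - TG/5 (withheld with a
validity flag at TG >= 400 mg/dL), non-HDL-C = TC - HDL-C, HOMA-IR =
insulin (uIU/mL) * glucose (mmol/L) / 22.5 with glucose converted from mg/dL
by * 0.0555, plus cholesterol:HDL, TG:HDL and leptin:adiponectin ratios
(leptin ng/mL vs adiponectin ug/mL harmonized to ng/mL before the ratio).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GLUCOSE_MGDL_TO_MMOLL",
    "FRIEDEWALD_TG_LIMIT",
    "ANALYTES",
    "ReplicateResult",
    "select_replicates",
    "plate_normalize",
    "flag_outliers",
    "derive_panel",
    "process_replicates",
    "derive_panel_table",
]

GLUCOSE_MGDL_TO_MMOLL = 0.0555
FRIEDEWALD_TG_LIMIT = 400.0

#: measured analyte panel (column names used throughout the package)
ANALYTES = (
    "glucose",
    "insulin",
    "leptin",
    "adiponectin",
    "triglycerides",
    "total_cholesterol",
    "hdl_c",
    "igfbp1",
    "il10",
    "crp",
    "resistin",
)


@dataclass(frozen=True)
class ReplicateResult:
    value: float
    cv: float
    flag: str  # "ok" | "best_pair" | "fail"


def _cv(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0:
        return 0.0 if np.all(values == 0) else math.inf
    return float(values.std(ddof=1) / m)


def select_replicates(values: Sequence[float], cv_threshold: float = 0.05) -> ReplicateResult:
    """Replicate selection: mean of all if CV < threshold, else best pair.

    For triplicates failing the CV rule the pair with minimal CV is used; if
    even that pair fails, its mean is retained with flag ``fail``.
    """
    vals = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 replicates")
    cv_all = _cv(vals)
    if cv_all < cv_threshold:
        return ReplicateResult(float(vals.mean()), cv_all, "ok")
    if vals.size == 2:
        return ReplicateResult(float(vals.mean()), cv_all, "fail")
    best = min(itertools.combinations(vals, 2), key=lambda p: _cv(np.asarray(p)))
    best = np.asarray(best)
    cv_pair = _cv(best)
    flag = "best_pair" if cv_pair < cv_threshold else "fail"
    return ReplicateResult(float(best.mean()), cv_pair, flag)


def plate_normalize(
    values: Mapping[str, float],
    plate_ids: Mapping[str, str],
    controls: Mapping[str, float],
) -> dict[str, float]:
    """Multiplicative plate correction against the internal control.

    adjusted = value * geometric_mean(all plate controls) / control(own plate).
    """
    for plate, c in controls.items():
        if not (c > 0):
            raise ValueError(f"plate {plate!r}: control must be positive")
    missing = {plate_ids[k] for k in values} - set(controls)
    if missing:
        raise ValueError(f"plates without a control: {sorted(missing)}")
    gm = math.exp(np.mean([math.log(c) for c in controls.values()]))
    return {k: v * gm / controls[plate_ids[k]] for k, v in values.items()}


def flag_outliers(values: Sequence[float]) -> np.ndarray:
    """Tukey-fence outlier flags (1.5 * IQR beyond Q1/Q3).

    Quartiles use linear interpolation between order statistics.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise ValueError("need at least 4 values for the IQR screen")
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    return (vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)


def derive_panel(panel: Mapping[str, float]) -> dict[str, float]:
    """Derived biomarkers from one dyad's QC'd panel.

    Each derived value is present only when its inputs are; ratios with a
    non-positive denominator are withheld. Returns NaN for absent values plus
    a ``friedewald_valid`` flag (False when LDL-C was withheld at TG >= 400).
    """

    def get(name: str) -> float:
        v = panel.get(name)
        return float(v) if v is not None and np.isfinite(v) else math.nan

    tc, hdl, tg = get("total_cholesterol"), get("hdl_c"), get("triglycerides")
    glucose, insulin = get("glucose"), get("insulin")
    leptin, adiponectin = get("leptin"), get("adiponectin")

    out: dict[str, float] = {
        "ldl_c": math.nan,
        "non_hdl_c": math.nan,
        "homa_ir": math.nan,
        "chol_hdl_ratio": math.nan,
        "tg_hdl_ratio": math.nan,
        "leptin_adiponectin_ratio": math.nan,
        "friedewald_valid": True,
    }
    if not math.isnan(tc) and not math.isnan(hdl):
        out["non_hdl_c"] = tc - hdl
        if not math.isnan(tg):
            if tg >= FRIEDEWALD_TG_LIMIT:
                out["friedewald_valid"] = False
            else:
                out["ldl_c"] = tc - hdl - tg / 5.0
    if not math.isnan(insulin) and not math.isnan(glucose):
        out["homa_ir"] = insulin * (glucose * GLUCOSE_MGDL_TO_MMOLL) / 22.5
    if not math.isnan(tc) and not math.isnan(hdl) and hdl > 0:
        out["chol_hdl_ratio"] = tc / hdl
    if not math.isnan(tg) and not math.isnan(hdl) and hdl > 0:
        out["tg_hdl_ratio"] = tg / hdl
    if not math.isnan(leptin) and not math.isnan(adiponectin) and adiponectin > 0:
        # leptin ng/mL over adiponectin ug/mL -> ng/mL
        out["leptin_adiponectin_ratio"] = leptin / (adiponectin * 1000.0)
    return out


def process_replicates(
    replicates: pd.DataFrame,
    controls: pd.DataFrame,
    cv_thresholds: Mapping[str, float] | None = None,
    default_cv_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full lab QC: replicate selection then plate normalization, per analyte.

    ``replicates`` has columns dyad_id, analyte, plate_id, rep1, rep2[, rep3];
    ``controls`` has columns plate_id, control. Returns one row per dyad with
    one column per analyte plus ``<analyte>_cv_flag`` QC columns.
    """
    cv_thresholds = dict(cv_thresholds or {})
    control_map = dict(zip(controls["plate_id"], controls["control"].astype(float)))
    rep_cols = [c for c in ("rep1", "rep2", "rep3") if c in replicates.columns]

    rows: dict[str, dict[str, float | str]] = {}
    for analyte, grp in replicates.groupby("analyte", sort=False):
        thr = cv_thresholds.get(str(analyte), default_cv_threshold)
        values: dict[str, float] = {}
        plates: dict[str, str] = {}
        flags: dict[str, str] = {}
        for rec in grp.itertuples(index=False):
            reps = [getattr(rec, c) for c in rep_cols]
            reps = [r for r in reps if r is not None and np.isfinite(r)]
            res = select_replicates(reps, cv_threshold=thr)
            values[rec.dyad_id] = res.value
            plates[rec.dyad_id] = rec.plate_id
            flags[rec.dyad_id] = res.flag
        adjusted = plate_normalize(values, plates, control_map)
        for dyad, v in adjusted.items():
            row = rows.setdefault(dyad, {"dyad_id": dyad})
            row[str(analyte)] = v
            row[f"{analyte}_cv_flag"] = flags[dyad]
    out = pd.DataFrame(list(rows.values()))
    return out.sort_values("dyad_id").reset_index(drop=True)


def derive_panel_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`derive_panel` over a QC'd panel table; keeps analyte
    columns and appends the derived ones."""
    derived = pd.DataFrame.from_records(
        [derive_panel(row) for row in panel.to_dict("records")]
    )
    return pd.concat([panel.reset_index(drop=True), derived], axis=1)
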