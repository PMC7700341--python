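"""Composite biomarker indices.

Biomarkers of different units are combined by z-standardizing each component
over the dyads that have it (sample SD, n-1) and summing with sign
corrections: components that associate inversely with the construct are
multiplied by -1 before summing. Default compositions:

* metabolic: glucose, insulin, leptin, leptin:adiponectin, TG:HDL-C, HOMA-IR
  (all +);
* lipid: HDL-C (-), LDL-C, non-HDL-C, cholesterol:HDL-C, triglycerides (+);
* anti-inflammatory: adiponectin, IGFBP-1, IL-10 (+), CRP, resistin (-).

Two scalings are provided: ``zsum`` (sum of signed z-scores; mean 0 over the
standardization set) and ``tscore`` (sum of per-component T-scores
50 + 10 * sign * z; mean 50k for k components). They are affinely equivalent
and induce the same dyad ordering. An index value is emitted only for dyads
with every component present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IndexSpec",
    "METABOLIC_INDEX",
    "LIPID_INDEX",
    "ANTI_INFLAMMATORY_INDEX",
    "DEFAULT_INDEX_SPECS",
    "zstandardize",
    "standardize_matrix",
    "build_index",
    "build_all_indices",
]


@dataclass(frozen=True)
class IndexSpec:
    """Named composite: component names with signs (+1/-1) and a scaling mode."""

    name: str
    components: tuple[tuple[str, int], ...]
    scaling: str = "zsum"  # "zsum" | "tscore"

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ValueError("an index needs at least 2 components")
        if any(sign not in (1, -1) for _, sign in self.components):
            raise ValueError("component signs must be +1 or -1")
        if self.scaling not in ("zsum", "tscore"):
            raise ValueError(f"unknown scaling {self.scaling!r}")

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.components)


METABOLIC_INDEX = IndexSpec(
    "metabolic",
    (
        ("glucose", 1),
        ("insulin", 1),
        ("leptin", 1),
        ("leptin_adiponectin_ratio", 1),
        ("tg_hdl_ratio", 1),
        ("homa_ir", 1),
    ),
)

LIPID_INDEX = IndexSpec(
    "lipid",
    (
        ("hdl_c", -1),
        ("ldl_c", 1),
        ("non_hdl_c", 1),
        ("chol_hdl_ratio", 1),
        ("triglycerides", 1),
    ),
)

ANTI_INFLAMMATORY_INDEX = IndexSpec(
    "anti_inflammatory",
    (
        ("adiponectin", 1),
        ("igfbp1", 1),
        ("il10", 1),
        ("crp", -1),
        ("resistin", -1),
    ),
)

DEFAULT_INDEX_SPECS = (METABOLIC_INDEX, LIPID_INDEX, ANTI_INFLAMMATORY_INDEX)


def zstandardize(column: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """(z-values, mean, sd) with sample (n-1) SD; NaNs pass through.

    Raises on zero variance (a constant column carries no information).
    """
    x = np.asarray(column, dtype=float)
    obs = x[np.isfinite(x)]
    if obs.size < 2:
        raise ValueError("need at least 2 observed values")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance: cannot z-standardize a constant column")
    return (x - mean) / sd, mean, sd


def standardize_matrix(
    panel: pd.DataFrame, columns: Iterable[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-standardize each named column over its observed dyads.

    Returns (z-matrix with the same index, per-component mean/sd table).
    """
    zcols, stats = {}, []
    for col in columns:
        z, mean, sd = zstandardize(panel[col].to_numpy(dtype=float))
        zcols[col] = z
        stats.append({"component": col, "mean": mean, "sd": sd})
    return pd.DataFrame(zcols, index=panel.index), pd.DataFrame(stats)


def build_index(zmatrix: pd.DataFrame, spec: IndexSpec, scaling: str | None = None) -> pd.Series:
    """Signed sum of component z-scores (or T-scores) per dyad.

    Dyads missing any component get NaN (complete-case per index).
    """
    scaling = scaling or spec.scaling
    missing = [c for c in spec.component_names if c not in zmatrix.columns]
    if missing:
        raise KeyError(f"index {spec.name!r}: unresolvable components {missing}")
    parts = []
    for name, sign in spec.components:
        z = zmatrix[name].astype(float)
        parts.append(50.0 + 10.0 * sign * z if scaling == "tscore" else sign * z)
    total = parts[0].copy()
    for p in parts[1:]:
        total = total + p
    total.name = spec.name
    return total


def build_all_indices(
    panel: pd.DataFrame,
    specs: Sequence[IndexSpec] = DEFAULT_INDEX_SPECS,
    scaling: str | None = None,
    id_col: str = "dyad_id",
) -> pd.DataFrame:
    """Standardize every component used by ``specs`` and build each index.

    Returns a table with dyad_id and one column per index (NaN where any
    component is missing).
    """
    needed = sorted({name for spec in specs for name in spec.component_names})
    zmat, _ = standardize_matrix(panel, needed)
    out = pd.DataFrame({id_col: panel[id_col].to_numpy()}, index=panel.index)
    for spec in specs:
        out[spec.name] = build_index(zmat, spec, scaling=scaling)
    return out.reset_index(drop=True)
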