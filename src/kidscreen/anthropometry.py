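"""Pediatric anthropometry: BMI, LMS growth-reference z-scores/percentiles,
weight-status categories and waist-to-height ratio.

The LMS method maps a measurement ``x`` to a z-score through age- and
sex-specific parameters: a Box-Cox power L, the median M and a coefficient of
variation S::

    z = ((x/M)**L - 1) / (L*S)        for L != 0
    z = ln(x/M) / S                   for L == 0

Percentiles are the standard-normal CDF of z (times 100). Weight status uses
the BMI-for-age percentile cut points: obesity >= 95th, overweight 85th to
<95th, normal 5th to <85th, underweight < 5th.

A synthetic-but-plausible packaged LMS table (``data/lms_bmi_synthetic.csv``,
ages 24-84 months, both sexes) supports offline use; genuine reference tables
in the same ``sex,agemos,L,M,S`` column layout load through the same reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "compute_bmi",
    "lms_z",
    "lms_inverse",
    "z_to_percentile",
    "classify_weight",
    "waist_to_height",
    "LmsReference",
    "derive_anthro",
]

_CATEGORIES = ("underweight", "normal", "overweight", "obesity")


def compute_bmi(weight: float, height: float) -> float:
    """BMI in kg/m^2 from weight (kg) and height (cm)."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    return weight / (height / 100.0) ** 2


def lms_z(x, L, M, S):
    """LMS z-score of measurement ``x`` given Box-Cox parameters.

    Implemented with expm1 so the power branch is numerically continuous in L
    at L = 0, where it reduces to ln(x/M)/S.
    """
    x, L, M, S = (np.asarray(a, dtype=float) for a in (x, L, M, S))
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    if np.any(x <= 0):
        raise ValueError("measurement must be positive")
    logr = np.log(x / M)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(L == 0, logr / S, np.expm1(L * logr) / (np.where(L == 0, 1.0, L) * S))
    return z if z.shape else float(z)


def lms_inverse(z, L, M, S):
    """Measurement whose LMS z-score is ``z``: M*(1 + L*S*z)**(1/L), or
    M*exp(S*z) at L = 0. Requires 1 + L*S*z > 0 when L != 0."""
    z, L, M, S = (np.asarray(a, dtype=float) for a in (z, L, M, S))
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    arg = 1.0 + L * S * z
    if np.any((L != 0) & (arg <= 0)):
        raise ValueError("z outside the valid LMS domain: 1 + L*S*z must be > 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(
            L == 0,
            M * np.exp(S * z),
            M * np.exp(np.log1p(np.where(L == 0, 0.0, L) * S * z) / np.where(L == 0, 1.0, L)),
        )
    return x if x.shape else float(x)


def z_to_percentile(z):
    """Percentile (0-100) as 100 * Phi(z)."""
    z = np.asarray(z, dtype=float)
    p = 100.0 * norm.cdf(z)
    return p if p.shape else float(p)


def classify_weight(percentile):
    """Weight-status category from a BMI-for-age percentile.

    >= 95 obesity; [85, 95) overweight; [5, 85) normal; < 5 underweight.
    """
    p = np.asarray(percentile, dtype=float)
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percentile must lie in [0, 100]")
    idx = np.searchsorted([5.0, 85.0, 95.0], p, side="right")
    cat = np.asarray(_CATEGORIES)[idx]
    return cat if cat.shape else str(cat)


def waist_to_height(waist, height):
    """Waist-to-height ratio as 100 * waist (cm) / height (cm)."""
    waist = np.asarray(waist, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise ValueError("height must be positive")
    r = 100.0 * waist / height
    return r if r.shape else float(r)


@dataclass(frozen=True)
class LmsReference:
    """Sex- and age-indexed (L, M, S) table with linear interpolation in age.

    Interpolation is applied to L, M and S separately; querying a tabulated
    knot age returns that row exactly.
    """

    table: pd.DataFrame  # columns sex, agemos, L, M, S

    def __post_init__(self) -> None:
        required = {"sex", "agemos", "L", "M", "S"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"LMS table missing columns: {sorted(missing)}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ValueError("LMS table requires M > 0 and S > 0")
        for _, grp in self.table.groupby("sex"):
            ages = grp["agemos"].to_numpy()
            if not np.all(np.diff(ages) > 0):
                raise ValueError("ages must be strictly increasing within sex")

    @classmethod
    def from_csv(cls, path: str) -> "LmsReference":
        return cls(pd.read_csv(path).sort_values(["sex", "agemos"]).reset_index(drop=True))

    @classmethod
    def default(cls) -> "LmsReference":
        """The packaged synthetic BMI-for-age fixture (24-84 months)."""
        with resources.as_file(
            resources.files("kidscreen.data") / "lms_bmi_synthetic.csv"
        ) as p:
            return cls.from_csv(str(p))

    def age_span(self, sex: str) -> tuple[float, float]:
        ages = self.table.loc[self.table["sex"] == sex, "agemos"]
        if ages.empty:
            raise KeyError(f"no LMS rows for sex {sex!r}")
        return float(ages.min()), float(ages.max())

    def lookup(self, sex, agemos):
        """(L, M, S) at the given sex/age, linearly interpolated in age."""
        sex = np.atleast_1d(np.asarray(sex, dtype=object))
        age = np.atleast_1d(np.asarray(agemos, dtype=float))
        sex, age = np.broadcast_arrays(sex, age)
        L = np.empty(age.shape)
        M = np.empty(age.shape)
        S = np.empty(age.shape)
        for s in np.unique(sex):
            grp = self.table[self.table["sex"] == s]
            if grp.empty:
                raise KeyError(f"no LMS rows for sex {s!r}")
            knots = grp["agemos"].to_numpy()
            mask = sex == s
            a = age[mask]
            if np.any((a < knots[0]) | (a > knots[-1])):
                raise ValueError(
                    f"age outside the reference span [{knots[0]}, {knots[-1]}] for sex {s!r}"
                )
            L[mask] = np.interp(a, knots, grp["L"].to_numpy())
            M[mask] = np.interp(a, knots, grp["M"].to_numpy())
            S[mask] = np.interp(a, knots, grp["S"].to_numpy())
        if L.size == 1 and np.isscalar(agemos):
            return float(L[0]), float(M[0]), float(S[0])
        return L, M, S


def derive_anthro(records: pd.DataFrame, lms: LmsReference | None = None) -> pd.DataFrame:
    """Per-dyad derived anthropometry table.

    ``records`` needs columns dyad_id, sex, age_months, weight and either
    single height/waist columns or paired repeats height1/height2 and
    waist1/waist2 (repeats are averaged; a single available repeat is used
    as-is). Returns dyad_id, bmi, bmi_z, bmi_percentile, whtr, category.
    """
    if lms is None:
        lms = LmsReference.default()

    def _avg(df: pd.DataFrame, stem: str) -> np.ndarray:
        if stem in df.columns:
            return df[stem].to_numpy(dtype=float)
        pair = df[[f"{stem}1", f"{stem}2"]]
        return pair.mean(axis=1, skipna=True).to_numpy(dtype=float)

    height = _avg(records, "height")
    waist = _avg(records, "waist")
    weight = records["weight"].to_numpy(dtype=float)
    bmi = compute_bmi(weight, height)
    L, M, S = lms.lookup(records["sex"].to_numpy(), records["age_months"].to_numpy())
    bmi_z = lms_z(bmi, L, M, S)
    pct = z_to_percentile(bmi_z)
    return pd.DataFrame(
        {
            "dyad_id": records["dyad_id"].to_numpy(),
            "bmi": bmi,
            "bmi_z": bmi_z,
            "bmi_percentile": pct,
            "whtr": waist_to_height(waist, height),
            "category": classify_weight(pct),
        }
    )
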