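"""Synthetic parent/child dyad cohorts.

The generator emulates the statistical structure the validation pipeline
assumes, so every stage is testable offline:

* a latent healthful-environment factor U ~ N(0, 1) per dyad drives the
  informative instrument items through an ordered five-level
  (proportional-odds) model whose baseline propensities concentrate
  responses in options 3-4; non-informative items are pure noise;
* child BMI z-score is ``-effect_beta`` times the standardized informative
  score signal plus independent noise, realized to height/weight through the
  inverse LMS transform against the packaged reference; waist tracks a
  waist-to-height ratio near 50 with a component linked to the same signal;
* biomarkers are log-normal with log-mean shifted by a signed loading times
  the BMI z-score (anti-inflammatory analytes load negatively), measured in
  triplicate (IGFBP-1 in duplicate) with multiplicative plate effects whose
  internal controls carry the same plate factor;
* dropout and per-assay missingness are MCAR at configured rates (an
  optional MAR switch ties dropout to parent age for attrition power
  checks).

A truth table (latent factor, score signal, true BMI z) rides along for
testing only and is never consumed by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .anthropometry import LmsReference, lms_inverse
from .instrument import Codebook, ItemDef

__all__ = [
    "SimConfig",
    "CohortBundle",
    "default_codebook",
    "generate",
    "emulate_study_shape",
    "write_tables",
    "DEFAULT_BIOMARKER_LOADINGS",
    "BIOMARKER_SCALES",
]

_CONSTRUCTS = (
    "Vegetables",
    "Fruit",
    "Beans",
    "Dairy",
    "Whole Grains",
    "Sugar Sweetened Beverages",
    "Fat/Saturated Fat",
    "Snack Foods",
    "Screen Time",
    "Sleep",
)

#: signed latent loadings (sign = direction of association with child BMI)
DEFAULT_BIOMARKER_LOADINGS: dict[str, float] = {
    "glucose": 0.5,
    "insulin": 0.5,
    "leptin": 0.6,
    "adiponectin": -0.5,
    "triglycerides": 0.5,
    "total_cholesterol": 0.4,
    "hdl_c": -0.5,
    "igfbp1": -0.5,
    "il10": -0.4,
    "crp": 0.5,
    "resistin": 0.4,
}

#: marginal scales: analyte -> (median in assay units, log-SD)
BIOMARKER_SCALES: dict[str, tuple[float, float]] = {
    "glucose": (85.0, 0.07),  # mg/dL
    "insulin": (5.0, 0.45),  # uIU/mL
    "leptin": (3.0, 0.55),  # ng/mL
    "adiponectin": (10.0, 0.30),  # ug/mL
    "triglycerides": (60.0, 0.35),  # mg/dL
    "total_cholesterol": (160.0, 0.14),  # mg/dL
    "hdl_c": (50.0, 0.16),  # mg/dL
    "igfbp1": (30.0, 0.50),  # ng/mL
    "il10": (2.0, 0.40),  # pg/mL
    "crp": (0.5, 0.80),  # mg/L
    "resistin": (10.0, 0.30),  # ng/mL
}

#: baseline cumulative propensities over the 5 ordered levels (skewed to 3-4)
_BASE_CUM = np.array([0.02, 0.10, 0.40, 0.80])
_THRESHOLDS = np.log(_BASE_CUM / (1.0 - _BASE_CUM))

_DUPLICATE_ANALYTES = ("igfbp1",)


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped generator configuration.

    Defaults mirror the study conditions: 273 enrolled dyads with 78%
    retention (~206 completing), a 45-item pool with an 18-item informative
    core, ~200 of 206 with anthropometry, ~190 giving blood and ~15% of
    assays missing (per-biomarker n ~= 159-163), 7 assay plates.
    """

    n_enrolled: int = 273
    retention: float = 206.0 / 273.0
    n_items: int = 45
    n_informative_items: int = 18
    item_loading: float = 0.31
    effect_beta: float = 0.5
    biomarker_loadings: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_LOADINGS)
    )
    missing_anthro: float = 6.0 / 206.0
    blood_given: float = 190.0 / 206.0
    missing_biomarker: float = 0.15
    missing_biomarker_shared: float = 0.12
    missing_item: float = 0.0005
    plates: int = 7
    plate_sd: float = 0.05
    replicate_cv: float = 0.03
    mar_attrition: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "retention",
            "missing_anthro",
            "blood_given",
            "missing_biomarker",
            "missing_biomarker_shared",
            "missing_item",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.missing_biomarker_shared > self.missing_biomarker:
            raise ValueError("missing_biomarker_shared cannot exceed missing_biomarker")
        if self.n_informative_items > self.n_items:
            raise ValueError("n_informative_items cannot exceed n_items")
        if not (0.0 <= self.item_loading < 1.0):
            raise ValueError("item_loading is a standardized loading in [0, 1)")
        if self.plates < 1 or self.n_items < 1 or self.n_enrolled < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class CohortBundle:
    codebook: Codebook
    informative_items: tuple[str, ...]
    responses: pd.DataFrame
    anthro: pd.DataFrame
    replicates: pd.DataFrame
    controls: pd.DataFrame
    demographics: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def default_codebook(n_items: int = 45) -> Codebook:
    """Deterministic 45-item pool cycling through 10 behavioral constructs.

    Odd-indexed items carry a half-point option score so instrument totals
    land on the half-point grid, as observed totals do.
    """
    items = []
    for i in range(n_items):
        scores = (1.0, 2.0, 3.5, 4.0, 5.0) if i % 2 else (1.0, 2.0, 3.0, 4.0, 5.0)
        items.append(
            ItemDef(
                id=f"item{i + 1:02d}",
                construct=_CONSTRUCTS[i % len(_CONSTRUCTS)],
                prompt=f"behavior item {i + 1}",
                option_scores={str(k + 1): s for k, s in enumerate(scores)},
            )
        )
    return Codebook(items=tuple(items), version_tag=f"synthetic-{n_items}")


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def generate(config: SimConfig, lms: LmsReference | None = None) -> CohortBundle:
    """Draw one cohort; fixed config (including seed) gives identical tables."""
    rng = np.random.default_rng(config.seed)
    if lms is None:
        lms = LmsReference.default()
    n = config.n_enrolled
    dyads = np.array([f"d{i + 1:04d}" for i in range(n)])

    # demographics (all enrolled) and completion
    parent_age = rng.normal(33.6, 6.0, n)
    employment = rng.choice(
        ["unemployed", "seasonal", "full_time"], size=n, p=[0.71, 0.17, 0.12]
    )
    sex = np.where(rng.permutation(n) < n // 2, "female", "male")
    age_months = rng.uniform(36.0, 72.0, n)
    if config.mar_attrition:
        # older parents slightly more likely to stay, as attrition analyses find
        logits = _logit(config.retention) + 0.4 * (parent_age - 33.6) / 6.0
        completed = rng.random(n) < 1.0 / (1.0 + np.exp(-logits))
    else:
        completed = rng.random(n) < config.retention
    demographics = pd.DataFrame(
        {
            "dyad_id": dyads,
            "completed": completed,
            "parent_age": parent_age,
            "employment": employment,
            "child_sex": sex,
            "child_age_months": age_months,
        }
    )

    # latent factor and ordered-categorical item responses; item_loading is
    # the standardized loading (correlation of the item's latent propensity
    # with U), converted to a slope against the unit-scale logistic noise
    U = rng.normal(0.0, 1.0, n)
    codebook = default_codebook(config.n_items)
    informative = codebook.item_ids[: config.n_informative_items]
    lam = config.item_loading
    slope = lam * (np.pi / np.sqrt(3.0)) / np.sqrt(1.0 - lam**2)
    loadings = np.zeros(config.n_items)
    loadings[: config.n_informative_items] = slope
    eps = rng.logistic(0.0, 1.0, (n, config.n_items))
    latent = U[:, None] * loadings[None, :] + eps
    levels = 1 + (latent[:, :, None] > _THRESHOLDS[None, None, :]).sum(axis=2)
    score_maps = np.array(
        [[codebook.items[j].option_scores[str(k)] for k in range(1, 6)] for j in range(config.n_items)]
    )
    scores = np.take_along_axis(
        score_maps[None, :, :].repeat(n, axis=0), levels[:, :, None] - 1, axis=2
    )[:, :, 0]

    # score signal and true BMI z
    signal = scores[:, : config.n_informative_items].sum(axis=1)
    zsig = (signal - signal.mean()) / signal.std(ddof=1)
    beta = config.effect_beta
    noise_sd = np.sqrt(max(0.0, 1.0 - beta**2))
    bmi_z = np.clip(-beta * zsig + noise_sd * rng.normal(0.0, 1.0, n), -4.0, 4.0)

    comp = completed
    comp_ids = dyads[comp]

    # responses for completers, sparse MCAR item missingness
    resp_scores = scores[comp].astype(float)
    item_mask = rng.random(resp_scores.shape) < config.missing_item
    resp_scores[item_mask] = np.nan
    responses = pd.DataFrame(resp_scores, columns=list(codebook.item_ids))
    responses.insert(0, "dyad_id", comp_ids)

    # anthropometry (completers minus MCAR misses), realized through the LMS
    # reference: BMI from the true z, weight from BMI and a simple growth curve
    have_anthro = rng.random(comp.sum()) < 1.0 - config.missing_anthro
    height_true = 95.0 + 0.55 * (age_months[comp] - 36.0) + rng.normal(0.0, 3.5, comp.sum())
    L, M, S = lms.lookup(sex[comp], age_months[comp])
    bmi_true = lms_inverse(bmi_z[comp], L, M, S)
    weight = np.round(bmi_true * (height_true / 100.0) ** 2, 1)
    waist_true = height_true / 100.0 * (
        50.0 + 1.8 * bmi_z[comp] + rng.normal(0.0, 1.5, comp.sum())
    )
    meas = rng.normal(0.0, 0.2, (comp.sum(), 4))  # repeat-measurement error, cm
    anthro = pd.DataFrame(
        {
            "dyad_id": comp_ids,
            "sex": sex[comp],
            "age_months": age_months[comp],
            "height1": np.round(height_true + meas[:, 0], 1),
            "height2": np.round(height_true + meas[:, 1], 1),
            "weight": weight,
            "waist1": np.round(waist_true + meas[:, 2], 1),
            "waist2": np.round(waist_true + meas[:, 3], 1),
        }
    )[have_anthro].reset_index(drop=True)

    # biomarker replicates with plate structure
    gave_blood = rng.random(comp.sum()) < config.blood_given
    donors = comp_ids[gave_blood]
    donor_bmi_z = bmi_z[comp][gave_blood]
    plate_ids = np.array([f"plate{(i % config.plates) + 1}" for i in range(donors.size)])
    plate_factor = np.exp(rng.normal(0.0, config.plate_sd, config.plates))
    plate_map = {f"plate{p + 1}": plate_factor[p] for p in range(config.plates)}
    # biomarker missingness is mostly shared within a dyad (insufficient
    # sample affects every assay) with a smaller analyte-specific component;
    # the two combine to the configured per-analyte rate
    shared = config.missing_biomarker_shared
    if shared >= 1.0:
        specific = 1.0
    else:
        specific = 1.0 - (1.0 - config.missing_biomarker) / (1.0 - shared)
    assay_ok = rng.random(donors.size) < 1.0 - shared
    rep_rows = []
    for analyte, loading in config.biomarker_loadings.items():
        median, sigma = BIOMARKER_SCALES[analyte]
        resid = np.sqrt(max(0.0, 1.0 - min(1.0, loading**2)))
        log_true = (
            np.log(median)
            + loading * sigma * donor_bmi_z
            + sigma * resid * rng.normal(0.0, 1.0, donors.size)
        )
        true_vals = np.exp(log_true)
        n_rep = 2 if analyte in _DUPLICATE_ANALYTES else 3
        present = assay_ok & (rng.random(donors.size) < 1.0 - specific)
        rep_noise = np.exp(rng.normal(0.0, config.replicate_cv, (donors.size, 3)))
        for i in np.flatnonzero(present):
            pf = plate_map[plate_ids[i]]
            reps = true_vals[i] * pf * rep_noise[i, :n_rep]
            rep_rows.append(
                {
                    "dyad_id": donors[i],
                    "analyte": analyte,
                    "plate_id": plate_ids[i],
                    "rep1": reps[0],
                    "rep2": reps[1],
                    "rep3": reps[2] if n_rep == 3 else np.nan,
                }
            )
    replicates = pd.DataFrame(
        rep_rows, columns=["dyad_id", "analyte", "plate_id", "rep1", "rep2", "rep3"]
    )
    controls = pd.DataFrame(
        {
            "plate_id": [f"plate{p + 1}" for p in range(config.plates)],
            "control": 100.0 * plate_factor,
        }
    )

    gave = np.zeros(n, dtype=bool)
    gave[np.isin(dyads, donors)] = True
    truth = pd.DataFrame(
        {
            "dyad_id": dyads,
            "completed": completed,
            "gave_blood": gave,
            "latent": U,
            "score_signal": signal,
            "bmi_z_true": bmi_z,
        }
    )

    return CohortBundle(
        codebook=codebook,
        informative_items=tuple(informative),
        responses=responses,
        anthro=anthro,
        replicates=replicates,
        controls=controls,
        demographics=demographics,
        truth=truth,
        config=config,
    )


def emulate_study_shape(config: SimConfig | None = None) -> dict[str, object]:
    """Realized cohort counts against the study-shaped expectations.

    Expected bands: ~206 completing of 273 enrolled, ~200 with anthropometry,
    ~190 donating blood, per-biomarker n ~= 159-163.
    """
    config = config or SimConfig()
    bundle = generate(config)
    n_complete = int(bundle.demographics["completed"].sum())
    per_analyte = bundle.replicates.groupby("analyte")["dyad_id"].nunique()
    n_blood = int(bundle.truth["gave_blood"].sum())
    expected_complete = config.n_enrolled * config.retention
    expected_anthro = expected_complete * (1.0 - config.missing_anthro)
    expected_blood = expected_complete * config.blood_given
    expected_biomarker = expected_blood * (1.0 - config.missing_biomarker)
    return {
        "n_enrolled": config.n_enrolled,
        "n_completing": n_complete,
        "expected_completing": expected_complete,
        "n_anthro": int(len(bundle.anthro)),
        "expected_anthro": expected_anthro,
        "n_blood": n_blood,
        "expected_blood": expected_blood,
        "biomarker_n_min": int(per_analyte.min()) if len(per_analyte) else 0,
        "biomarker_n_max": int(per_analyte.max()) if len(per_analyte) else 0,
        "expected_biomarker": expected_biomarker,
    }


def write_tables(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write the analysis tables plus the truth table as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.responses.to_csv(outdir / "responses.csv", index=False)
    bundle.anthro.to_csv(outdir / "anthro.csv", index=False)
    bundle.replicates.to_csv(outdir / "replicates.csv", index=False)
    bundle.controls.to_csv(outdir / "controls.csv", index=False)
    bundle.demographics.to_csv(outdir / "demographics.csv", index=False)
    bundle.truth.to_csv(outdir / "truth.csv", index=False)
    import json

    with open(outdir / "codebook.json", "w") as fh:
        json.dump(
            {
                "version_tag": bundle.codebook.version_tag,
                "items": [
                    {
                        "id": it.id,
                        "construct": it.construct,
                        "prompt": it.prompt,
                        "option_scores": dict(it.option_scores),
                    }
                    for it in bundle.codebook.items
                ],
            },
            fh,
            indent=1,
        )
    with open(outdir / "selected_items.json", "w") as fh:
        json.dump(list(bundle.informative_items), fh)
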