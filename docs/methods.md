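# Methods

## Instrument model

Items are coded on a five-point scale with the highest option the healthiest
behavior. Option scores are validated on a 0.5 grid in [1, 5]: observed
instrument totals are non-integer (e.g. 51.5), so half-point option coding
must be representable; the grid resolution is a module constant and the
validation is confined to the codebook loader. Totals are plain sums over a
selected item subset. Responses missing any subset item are flagged
incomplete and excluded from group assignment — a complete-case policy; no
imputation is attempted. Dichotomization is a step function: high iff
total ≥ threshold, with the threshold a parameter defaulting to 75.0 (the
boundary between the low 51.5–74.9 and high 75.0–80.5 score bands).

## Anthropometry

BMI is weight/(height/100)² with paired height and waist repeats averaged
first (a single available repeat is used as-is). The LMS transform is
implemented with `expm1`/`log1p` so the power branch is numerically
continuous in L at L = 0 and the inverse is exact on the valid domain
(1 + L·S·z > 0); round-trip error is below 1e−10 in tests. Reference (L, M,
S) values are linearly interpolated in age separately per parameter within
sex; a query at a tabulated knot returns that row exactly. Percentiles are
100·Φ(z) (normal CDF convention, not empirical rank), and weight categories
partition [0, 100] with boundaries exactly at the 5th, 85th and 95th
percentiles (boundary values belong to the upper category). The packaged
reference table is a synthetic-but-plausible BMI-for-age fixture covering
24–84 months for both sexes — smooth curves with a mid-childhood median
nadir — not a copy of any published table; genuine references in the same
`sex,agemos,L,M,S` layout load through the same reader. Extended/modified
z-scores for very high BMI are out of scope.

## Laboratory QC

Replicate CV is sample SD (n−1) over mean. If a triplicate's CV is below
the threshold (default 5%; configurable per analyte, e.g. 10% for IGFBP-1)
its mean is used; otherwise the pair with minimal CV is selected ("best 2 of
3"); a pair still failing is retained but flagged `fail` — exclusion is left
to the caller, since flagged-but-retained matches a reporting-first QC
posture. Plate normalization assumes a multiplicative immunoassay error
model: each value is scaled by (geometric mean of all plate controls)/(own
plate's control), so correction factors multiply to one across plates and
the adjustment is idempotent once controls are recomputed. Outliers use
Tukey fences at 1.5·IQR with quartiles by linear interpolation between order
statistics (the same convention as the descriptive statistics); outliers are
flagged, never removed. Friedewald LDL-C is withheld (with a validity flag)
at TG ≥ 400 mg/dL; HOMA-IR converts glucose from mg/dL with the factor
0.0555 mmol/L per mg/dL; leptin (ng/mL) and adiponectin (μg/mL) are
harmonized to ng/mL before their ratio.

## Composite indices

Each component is z-standardized with sample (n−1) SD over the dyads that
have it (complete-case per component), and an index value is produced only
for dyads with every component present. This mirrors per-index analysis
sets whose n varies with assay availability. Sign corrections multiply
inversely-associated components by −1 before summing: HDL-C in the lipid
index; CRP and resistin in the anti-inflammatory index. Two scalings are
offered — `zsum` (default; the index is a sum of signed z-scores, mean 0
over the standardization set) and `tscore` (sum of per-component
50 + 10·sign·z values, mean 50k for k components). The two are affinely
equivalent and order dyads identically; `tscore` exists because summed
T-scores are the natural reading of index magnitudes in the several-hundred
range sometimes reported for 5–6 component indices, while plain z-sums are
the plainest reading of "sum of z-scores". No claim is made about which
scaling any particular published table used.

## Item screening

The published item-reduction procedure was a visual judgement over
per-category boxplots of adiposity markers. That is operationalized here as
a rank rule: an item is kept when, for at least one of BMI-for-age
percentile, BMI z and waist-to-height ratio, the Spearman correlation with
the item score satisfies ρ ≤ −ρ_min (default 0.05) **and** the one-sided
(negative-direction) p-value is ≤ α (default 0.05). The ρ_min floor keeps
trivially small trends out; the significance condition calibrates the null
keep-rate — with the ρ floor alone, sampling noise at n ≈ 200 would admit
roughly a quarter of pure-noise items per marker, which no visual screen
would accept. Decisions are invariant to strictly increasing transforms of
the markers and to exact duplication of dyads. Category discretization
merges levels observed fewer than `min_count` (default 5) times into the
nearest level, mirroring how sparse boxplot categories would be pooled.
Pruning to the target instrument size (default 16–20 items) keeps the
strongest (most negative) ρ with lexicographic item-id tie-breaks for
determinism; an optional per-construct cap limits redundancy within a
behavioral domain. Boxplot rendering is provided for visual parity only.

## Validation statistics

Outcome differences between the low and high score groups use the
Kruskal–Wallis test on midranks with the standard tie correction and a
χ²(k−1) reference distribution; with two groups this is the two-sided
Wilcoxon rank-sum test (normal approximation, no continuity correction) —
an algebraic identity the tests verify to 1e−9. An all-identical pooled
sample is the exchangeable degenerate case and returns (H, p) = (0, 1)
directly. Descriptives are medians and linearly interpolated quartiles.
Tests are two-sided at α = 0.05 with no multiplicity adjustment (per-outcome
reporting). A one-way ANOVA is available as an optional parametric
cross-check, never a decision rule. Attrition comparisons use Pearson
chi-square for categorical variables and Welch's t for continuous ones;
single-level variables are skipped with a reason. Outcomes for which either
group has fewer than two members are reported untested rather than erroring,
so a degenerate grouping still yields a complete report.

## Synthetic cohort generator

The generator encodes the structure the validation is designed to detect.
Per dyad, a latent healthful-environment factor U ~ N(0, 1) drives the
informative items through a proportional-odds model: item level =
1 + #{thresholds below slope·U + logistic noise}, with baseline cumulative
propensities (0.02, 0.10, 0.40, 0.80) concentrating responses in options
3–4. `item_loading` is the standardized loading — the correlation between
an item's latent propensity and U — converted internally to the logistic
slope λ·(π/√3)/√(1−λ²). The default 0.31 was calibrated so 18-item totals
span roughly 51–81 with ~10–13% of dyads at or above 75, the score shape the
validation design anticipates; the item-screen recovery scenario uses 0.3.

Child BMI z is −`effect_beta` times the standardized informative-item total
plus independent N(0, √(1−β²)) noise (clipped to ±4 to stay inside the LMS
domain), realized to a measurable BMI through the inverse LMS transform at
the child's age/sex, with weight back-computed from a simple height growth
curve (95 cm at 36 months + 0.55 cm/month + N(0, 3.5)). Waist tracks a
waist-to-height ratio near 50 with a 1.8·BMI-z component and N(0, 1.5)
noise; heights and waists carry two repeats with 0.2 cm measurement error,
and all recorded measures are rounded to 0.1 units as a field protocol
would.

Biomarkers are log-normal: log value = log(median) + loading·σ·BMI-z +
σ·√(1−loading²)·ε, so the signed `biomarker_loadings` entry is the
correlation between log concentration and BMI z (positive for glucose,
insulin, leptin, TG, total cholesterol, CRP, resistin; negative for HDL-C,
adiponectin, IGFBP-1, IL-10). Medians and log-SDs sit at mid-range
pediatric values (e.g. glucose 85 mg/dL, HDL-C 50 mg/dL, CRP 0.5 mg/L) and
are config-overridable; no claim is made of matching any specific
population's distributions. Assays run in triplicate (IGFBP-1 duplicate)
with multiplicative log-normal replicate noise at `replicate_cv` and 7
plates whose log-normal factors (SD `plate_sd`) also scale each plate's
internal control, making the plate adjustment exactly invertible up to the
geometric-mean convention.

Cohort accounting follows the study shape: 273 enrolled, Bernoulli
retention averaging ~206 completers, ~3% of completers missing
anthropometry (~200), ~92% donating blood (~190), and per-analyte
missingness of 15% split into a dyad-level shared component (default 0.12 —
the insufficient-sample mechanism, which also reproduces per-index analysis
sets of ~140–150) plus an analyte-specific remainder (per-biomarker
n ≈ 159–163). Missingness is MCAR by default; `mar_attrition` ties dropout
to parent age (older parents retained) for attrition-test power checks. The
truth table (U, score signal, true BMI z, donation flags) is for tests only
and is never read by analysis code.

## Problem sizes and numerical choices

Stochastic suites use study-sized cohorts (273 enrolled / ~206 completing):
20 seeds for direction-pattern and item-screen recovery checks and 1000
seeds for null type-I calibration in the test suite — at 200 seeds the
binomial Monte-Carlo error of a rejection-rate estimate (SE ≈ 0.015) is
comparable to the width of the acceptance band itself, so the larger run is
used as plain variance reduction; the acceptance script reports the
200-seed rate. Quartiles use linear interpolation everywhere. Zero-variance
columns are errors for z-standardization (no information) but benign for
outlier fences and rank tests (degenerate, handled explicitly). Random
number use is confined to `numpy.random.default_rng` seeded from
configuration, and a fixed configuration reproduces byte-identical tables.

## Known limitations

- The LMS fixture is synthetic; absolute z-scores/percentiles from it are
  internally consistent but not comparable to real growth references.
- The generator's MCAR missingness and single latent factor are idealized;
  passing pipeline tests demonstrate statistical behavior under these
  conditions, not robustness to informative missingness, multi-factor
  behavior structure, or real assay artifacts.
- The item screen's ρ_min/α rule is one defensible operationalization of a
  visual procedure; selected item sets will differ from any human-judged
  selection at the margin.
- Real-data medians and p-values from the motivating study design are not
  reproducible here because the human-subjects data are not available; the
  package validates the machinery, not the original cohort's numbers.
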