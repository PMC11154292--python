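# Methods

This note documents the statistical model, the synthetic-cohort
generator's emulation scope, the numerical choices, and the known
limitations of the `echowall` package.

## 1. Phenotypes and measurement layer

**GSM.** The gray-scale median of a region of interest (ROI) is the 50th
percentile of its pixel gray levels (0–255), computed with the midpoint
convention for even counts (`numpy.median`).  ROIs are rectangles
(half-open `[r0, r1) x [c0, c1)`) or polygons rasterized with
`skimage.draw.polygon`.

**Calibration.** Each image carries two reference readings: black (the
darkest section of the lumen, valid range 0–37) and white (the brightest
adventitia section, valid range 104–255).  Gray levels are mapped
affinely so that black → 0 and white → `W_target = 190`, the
conventional adventitia anchor for GSM normalization; calibrated values
are clipped at 0.

**Plaque-GSM selection rule.** Per side, the lesion with the largest
IMT among those with IMT ≥ 1.5 mm is the measurement plaque (ties broken
toward the lower GSM); across sides the *darker* (lower GSM) of the two
measurement plaques is the subject's plaque-GSM (ties toward the left
side).  Subjects without any eligible lesion have no plaque-GSM.

**IM-GSM.** Mean of the left and right plaque-free common-carotid
intima-media GSM; a single available side is used alone and flagged.

**A-priori calibration adjustment.** Raw GSM is residualized on the
per-image black and white references by OLS and re-centred on the grand
mean.  This removes, by construction, any linear dependence of GSM on
the calibration references while preserving the mean.  Missing values
propagate; a constant reference column triggers a warning and
passthrough.

**Reproducibility.** Scan–rescan agreement is summarized by the mean
absolute difference and the one-way random-effects single-measure ICC,
`(MSB − MSW) / (MSB + MSW)` for k = 2 ratings (cross-checked against
`pingouin`'s ICC(1,1) in the tests).

## 2. Synthetic cohort generator

The generator is the package's substitute for the original multicentre
cohort; its defaults *are* the study conditions.

**Structure.** 3188 subjects apportioned to six centres (five
countries) by largest-remainder rounding; exactly 2138 plaque carriers,
chosen as the top of a latent severity score so that prevalence is
exact.  Risk factors (latitude, sex, age, height, waist/hip ratio,
blood pressures, education, MCV, creatinine, lipid-lowering drug use,
smoking) are drawn per centre with fixed means/SDs.  Pack-years are
coded 0 for never smokers and 1–3 for tertiles among ever smokers.
58 nuisance columns (independent noise, every fourth binary) serve as
null candidates for the selection procedure.

**Outcome model (effective slopes).** The printed semi-standardized
slopes, per-predictor variance shares and outcome SDs are jointly
overdetermined for independent predictors, so the generator treats the
variance shares and the SDs as binding and derives each *effective*
slope as `sign(beta) * sqrt(R2_k) * sigma` applied to the
sample-standardized predictor.  The residual is scaled so the marginal
outcome SD is exact; consequently the population whole-model R² equals
the sum of the per-predictor shares (11.9 % for plaque-GSM, 19.8 % for
IM-GSM, matching the printed 12.0 %/19.7 % within rounding).  The
printed slopes are retained in the effect tables for reference.

**Cross-phenotype correlation.** The residual correlation between the
two GSM errors is solved empirically (on the realized predictor sets)
so that the *marginal* Pearson correlation among plaque carriers hits
the target r = 0.51.

**High burden.** High atherosclerotic burden is the upper quartile of
IMT_max.  The latent-logistic coefficients of the two GSM quartile
codes are obtained by solving a 2x2 omitted-variable system on
covariate-residualized quartile codes, so that the two *marginal*
covariate-adjusted ordinal models recover the configured per-quartile
odds ratios (0.79 for plaque-GSM, 1.12 for IM-GSM) despite the
phenotypes being correlated.  Adjustment covariates: latitude, sex,
age, educational level, pulse pressure (SBP − DBP), pack-years code.

**IMT values.** Millimetre IMT_max values respect the thresholds
exactly (plaque-free < 1.5, plaque carriers ≥ 1.5, high burden ≥ 2.5)
and are rank-ordered within groups by the generating severity score.
This is a deliberate simplification: the quartile code used as a GSM
determinant is the generating quartile of severity among carriers, not
re-derived from the millimetre values.

**Calibration confounding.** Per-image references are drawn uniformly
(black 0–37, white 104–255) and leak linearly into raw GSM
(slopes +0.15 and −0.08), giving the adjustment step real work to do.

**Repeat scans.** For an ICC target ρ, rescan pairs for n = 138
subjects are built as true value plus independent errors with
`sigma_e = sigma_b * sqrt((1 − ρ)/ρ)`, which makes the population
one-way ICC exactly ρ.

**Wall images.** Synthetic B-mode-like images use multiplicative
Rayleigh speckle pinned to the target median
(`(R / median(R))^dispersion * target`) on horizontal wall bands, with
elliptical plaque carve-outs.

## 3. Determinant selection

**Screening.** Univariate tests by candidate type (ANOVA for normal,
Kruskal–Wallis for skewed, chi-square for binary/categorical with exact
fallback for sparse tables) against a Bonferroni threshold of 0.0007
(73 comparisons).

**Stability selection.** 200 random half-splits; on each half a
forward/backward stepwise OLS (entry p = 0.05 via F-test on
orthonormalized candidates, stay p = 0.10) selects a model, and a
predictor is *validated* when it is selected on one half and confirmed
on the complementary half.  Predictors validated in ≥ 70 % of
iterations are retained.  The stepwise search is implemented with
incremental orthonormal-basis projections, making the 200-iteration
procedure run in seconds at n ≈ 3000 with 70+ candidates.

**Final model and partial R².** The retained predictors enter one OLS
model; each predictor's contribution is the *sequential* incremental R²
under a greedy decreasing-contribution ordering, which telescopes
exactly to the whole-model R² (the tests assert the identity at
1e-10).  Reported slopes are semi-standardized (outcome units per
predictor SD).

## 4. Risk models

**AUC comparison.** Each phenotype, median-dichotomized, is predicted
by a logistic model on its retained determinants over the common
complete-case set.  AUCs are empirical (midrank placements); variances
and the paired difference test use the Hajek-projection influence
values, `Var = (h·h)/n²`, which reproduces the classical DeLong
estimator up to a factor (m−1)/m per class (cross-checked against R's
`pROC` in the tests).  Logistic fits fall back to an escalating L2
penalty under separation and are flagged.

**Quartile models.** High burden is modelled (a) with the GSM quartile
as an ordinal 1–4 term plus standardized adjustment covariates (the
per-quartile OR), and (b) with 15 cell indicators for the 4x4
plaque-GSM x IM-GSM quartile grid (reference: plaque Q4, IM Q1).
Quartile codes use ties-to-lower boundaries
(`1 + (x>q1) + (x>q2) + (x>q3)`).  A quadratic quartile term per
phenotype is reported descriptively as a supplementary p-value.

## 5. Problem sizes and seeds

Default analysis sizes: n = 3188 (2138 plaque carriers), 200
stability-selection iterations, 138 rescan pairs.  All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; two
pipeline runs with the same configuration are byte-identical apart from
the manifest timestamp.  The acceptance script derives all child seeds
(< 2^31) from a single `--seed` via `numpy.random.SeedSequence`.

## 6. Limitations

- The generator emulates the *printed summary structure* of the study
  (variance shares, SDs, correlation, ORs, ICCs, counts), not its raw
  data; joint covariate distributions, missingness patterns and centre
  heterogeneity beyond means are simplified.
- Effective slopes override printed slopes where the two are jointly
  infeasible (see §2); the printed slopes remain available in the
  effect tables.
- IMT millimetre values are rank-consistent with the generating
  severity but not an independent biological model of wall thickness.
- The exact-test fallback in screening handles 2xK tables only; larger
  sparse tables use the chi-square approximation.
- The influence-based AUC variance differs from the classical DeLong
  normalization by (m−1)/m per class; negligible at the problem sizes
  used.
- Single-side IM-GSM values are used as-is (flagged), with no
  measurement-error correction.
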