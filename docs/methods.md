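# Methods

This note documents the models and procedures implemented in `reefkit`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate about real survey data.

## Resolving semi-quantitative cover records

Historical cover tables mix numerics, ranges, and the codes "R" (< 1% cover)
and "+" (1–5% cover); a blank cell means no survey was conducted and is kept
strictly distinct from a recorded 0%. A range resolves to its midpoint
(the median of an interval). Two distinct rules apply to the symbols:

* in the **total-cover** column, "R" → 0.5% and "+" → 3.0%;
* in **per-taxon** columns, symbols are resolved jointly: count R-units
  ("R" = 1, "+" = 6), take `diff = total − Σ(numeric taxa)`, and give each
  symbolic taxon `units × diff / n_units` when `diff > 0`, else 0.

Numeric entries are never rescaled, so a taxon sum may legitimately fall
short of (or, in raw data, exceed) the recorded total — only the
`diff ≤ 0 → 0` rule intervenes. An allocated "+" is not clamped to its
nominal 5% ceiling; the allocation rule is applied verbatim. When the gap is
positive the allocation conserves the total exactly, and it is equivariant
under relabeling of taxa; both are property-tested.

## Compositional treatment

Covers are proportions of a closed whole, so effects are estimated on log
ratios rather than raw percents. The composition is the 7 taxon groups plus
the coral-free base ("other benthic"); the additive log-ratio uses the base
as denominator. Zeros are replaced **multiplicatively**: each zero part
becomes δ = 0.0025 (half of the 0.5% recording resolution, on the
proportion scale) and nonzero parts shrink by (1 − kδ), which preserves
closure and all ratios among nonzero parts. A naive-substitution variant
exists behind the same interface but is not the default. Replacement
refuses a δ that is not below the smallest nonzero part, since that would
invert the ordering of parts.

Back-transformation of fitted curves inverts the alr (parts ∝ exp(coord),
denominator ∝ 1), normalizes the named parts to 100%, then reports any
cover below 0.25% — half the rounding error again — as 0, without
re-normalizing. The floor applies only to back-transformed model output,
never to observed data. Robust Aitchison distances are Euclidean distances
between row-centered log-ratio (rclr) rows of the zero-replaced matrix.

## Hierarchical Bayesian effect-size models

Three designs share one machinery:

* **harbor survey** — alr cover ~ Normal(μ, ε²), identity link, with fixed
  effects substrate (0 = artificial, 1 = natural reef), depth below LWL,
  survey year and the substrate interactions, plus random intercepts for
  the 11 survey sites and 5 survey methods;
* **block survey, cover** — same structure with a surface-processing
  indicator and years since installation, no random effects;
* **block survey, colonies** — colony density ~ Gamma(mean μ, variance ε²)
  with a log link, parameterized internally as shape μ²/ε², rate μ/ε².
  Zero densities are outside the gamma support and rejected with guidance;
  the generator draws strictly positive densities.

All covariates, including the binary indicators, are standardized to
(x − mean)/(2·SD) with the sample SD, which puts continuous slopes and
binary contrasts on one effect-size scale (SD 0.5). Interaction columns are
products of the standardized main effects, keeping main-effect
interpretation. Priors are Uniform(−10, 10) on cover coefficients,
Uniform(−20, 20) on colony coefficients, and Half-Cauchy with scale 10⁻² on
every scale parameter (ε, s_site, s_method). The Half-Cauchy scale is
unusually tight for an SD prior; it is implemented literally as the survey
protocol states it, with a config override, and the heavy Cauchy tail lets
the likelihood dominate in practice. A collinearity screen (VIFs from
auxiliary least-squares fits plus the full Pearson correlation matrix) is
provided as a report, not a gate.

**Sampling.** Gradient-based No-U-Turn sampling with analytic log-posterior
gradients (bounded coefficients via a scaled-logit transform, scales via
log transform, random effects non-centered). The protocol is five
independent runs — seeds expanded deterministically from one master seed —
each discarding 1000 tuning iterations (dual-averaging step-size
adaptation, target acceptance 0.8, with a diagonal mass matrix re-estimated
mid-tune) and retaining 2000 draws, pooled into 10,000. The sampler is
validated against closed-form Gaussian targets, and the per-model gradients
against finite differences.

**Summaries.** The HDI is the shortest contiguous interval containing
⌈mass·n⌉ sorted draws. An effect is *credible_positive/negative* when its
80% HDI lies strictly above/below zero; an endpoint exactly at zero counts
as overlap (conservative). Convergence uses the classical (non-split)
Gelman-Rubin PSRF across the five runs, matching the protocol's vintage;
identical chains give ≈ 1.0 and zero within-run variance flags the
parameter as infinite. Bayesian R² is per-draw
var(predicted)/(var(predicted) + residual variance) with the model-based
residual variance, reported as median and 95% HDI. Fits are bit-for-bit
reproducible under a fixed master seed.

## Ordination and permutation inference

nMDS minimizes Kruskal stress-1 by monotone-regression majorization
(SMACOF with isotonic disparities, via scikit-learn), restarted from random
configurations up to a restart budget (default 999; ordinations in the test
suite use far fewer) and keeping the lowest-stress solution, centered and
rotated to principal axes. Environmental vectors are least-squares
directions in the ordination plane with permutation p-values from shuffling
sample labels.

PERMANOVA partitions the Gower-centered inner-product matrix
G = −½·J·D²·J by sequential (Type-I) sums of squares in the entry order
substrate, year, depth, substrate:year, substrate:depth — year enters as a
numeric covariate, matching its role in the regression models, while
pairwise tests across years treat year as a grouping factor. Each term's SS
is tr(H_k G) − tr(H_{k−1} G) for cumulative hat matrices H_k; pseudo-F uses
the residual mean square; p-values come from free permutation of sample
rows, p = (exceedances + 1)/(perms + 1), with ties counted as exceedances.
The partition is verified against an independent group-sum formulation and
against exhaustive enumeration at small n, and the one-way path against
scikit-bio. Pairwise PERMANOVA runs the one-factor test per group pair and
Bonferroni-corrects by the number of tested pairs; groups with fewer than
two samples are skipped.

## Spline response curves

One-dimensional thin-plate regression splines: basis = intercept + linear
term + (k − 2) radial |x − κ|³ functions at quantile knots, constrained to
the polynomial null space, with the conditionally-positive-definite kernel
penalty. The covariate is internally mapped to [0, 1], which conditions the
kernel and makes fits exactly invariant to affine rescaling of x. The
penalty λ minimizes GCV(λ) = n·RSS/(n − tr H)² over 61 log-spaced points on
[10⁻⁶, 10⁶] plus bounded local refinement (deterministic). Reported EDF
excludes the intercept, so a straight line has EDF 1 and the maximum is
k − 1. Defaults: k = 10; a design with only seven distinct sampling depths
caps k at 7. Confidence bands are fitted ± 1.96·SE from the penalized-fit
(Bayesian) covariance; grid points outside the observed range are flagged
as extrapolation. λ → ∞ reproduces the least-squares line analytically,
and on simulated smooth truths the GCV choice beats both extremes
out-of-sample on average.

## Tide-pool net ecosystem calcification

During rim-exposed (stagnant) spans, advection is negligible and the
TA-anomaly method applies: NEC = −½·(ΔTA/Δt)·Z̄·ρ_water, giving
mmol CaCO₃ m⁻² h⁻¹ from TA in mmol kg⁻¹ (a reader warning fires above
10 mmol kg⁻¹, the usual sign of µmol units), depth in m and density in
kg m⁻³. A TA decrease means calcification and positive NEC, always. The TA
trend is the least-squares slope over a window of consecutive samples —
using all samples, not endpoints — that must lie inside a stagnant span and
cover more than 30 min; the NEC SE propagates the slope SE. With samples
every 10–12 min, three-sample windows span only 20–24 min, so the pipeline
default window is four samples (the window size is configurable and the
30-min rule is enforced either way). Density comes from the EOS-80 surface
polynomial (checked against published values; a constant override such as
1023 kg m⁻³ is available).

The light response is NEC(I) = a·tanh(I/I_k) + c — the
photosynthesis–irradiance analogue, chosen because the protocol names the
tanh form without a formula — or a straight line, selected by small-sample
AIC; a non-converging tanh fit falls back to linear with a warning. Daily
NEC integrates the fitted response over a 24-h light curve (trapezoid;
night values zero, gaps above 2 h rejected) and its SD is first-order delta
method through the integral's parameter gradient, verified against
Monte-Carlo propagation. Station comparisons fit per-station TA slopes, an
ANCOVA-style common-slope F-test on the time×station interaction under a
pooled residual variance, and Tukey-style pairwise slope contrasts via the
studentized-range distribution.

## Synthetic-data generators

The generators encode the study conditions as defaults and write a truth
sidecar sufficient to score recovery.

* **Harbor survey**: 11 sites alternating artificial/natural, 5 methods,
  1989–2018, depths on the −2/−5/−8 m grid, two records per site-year.
  Per-taxon alr coordinates follow the fixed-effects structure
  (default standardized effects −1.5, −1.0, −0.5, 0.8, 0.2, −0.4, with
  taxon-specific intercept offsets) plus site (SD 0.5) and method (SD 0.3)
  intercepts and residual SD 0.6; a joint inverse-alr maps the 7
  coordinates to percents, so log(taxon/other) recovers each coordinate
  exactly. Spans beginning at/after the 1998 bleaching year use the exactly
  linear mean (for recovery tests); longer spans replace the year terms
  with a drop of 2 alr units at bleaching followed by linear recovery
  (0.15/yr artificial vs 0.05/yr natural, capped at baseline) — the faster
  artificial-substrate recovery is thus a recoverable contrast. Cells are
  degraded to "R"/"+" only where the true value is below the symbol's
  definition (rates 0.3), and to ranges above 5% (rate 0.1).
* **Block survey**: the 2 × 3 × 3 = 18-quadrat layout per year over years
  1–18; cover effects (−1.0, 0.6, −0.5, 0.9, 0.0, 0.3) with residual SD
  0.5, colony effects (1.5, 0.5, −0.4, 0.7, 0.0, 0.2) with gamma variance
  1, strictly positive draws.
* **Tide pool**: sinusoidal-squared daytime light (peak 2000, 06:00–18:00),
  true tanh response a = 6, I_k = 500, c = −1 (mmol m⁻² h⁻¹), pool depth
  0.5 m, TA evolved through the anomaly relation on a fine grid during a
  3.5-h stagnant window, sampled every 10–12 min with 0.003 mmol kg⁻¹
  (≈ 3 µmol kg⁻¹) measurement noise. A campaign helper spans morning,
  midday, afternoon and night windows so the light response is identified
  over its full range; the sidecar stores the analytic daily integral of
  the true response on the day's light curve.

What these generators do **not** emulate: spatial autocorrelation between
neighboring sites, temporal autocorrelation of method deployment, taxon
covariance beyond the shared denominator, observer bias in symbol use, and
advective TA exchange. Passing recovery and calibration tests therefore
demonstrates correctness of the estimators under their own assumptions, not
robustness to these field realities.

## Problem sizes and numerical choices in the test suite

Calibration and recovery tests run at deliberately modest sizes chosen as a
package default: null calibration of the 80%-HDI rule uses 50 replicates of
the 6-year block design with a single 250-tune/500-draw run per fit (the
credibility rule depends only on pooled draws, not on the cross-run
diagnostic); parameter recovery uses 20 replicates (10-year design) plus a
hierarchical-model check on the harbor design; PERMANOVA null calibration
uses 100–200 replicates at 99 permutations. The full five-run,
10,000-draw protocol is exercised end-to-end on the block design, where
every Gelman-Rubin value rounds to 1.00. Permutation p-values are never
zero by construction ((exceedances + 1)/(perms + 1)); HDI computation
requires ≥ 100 draws; PERMANOVA tie handling uses a 10⁻⁸ tolerance;
GCV refinement is deterministic, so spline fits carry no seed.

## Known limitations

* The alr denominator is fixed to the other-benthic part; no ilr/clr model
  variants.
* PERMANOVA uses free permutation only (no restricted/strata permutation)
  and sequential SS only.
* The gamma colony model cannot represent zero densities; designs with
  empty quadrats need a hurdle extension.
* Daily NEC assumes the fitted light response is stationary across the day
  and ignores advection outside stagnant spans.
* The NUTS implementation targets the smooth, low-dimensional posteriors of
  these designs; it uses a diagonal mass matrix and is not tuned for
  strongly correlated or high-dimensional posteriors.
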