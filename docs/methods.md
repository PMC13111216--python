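# Methods

`mmpcr` implements an integrative modelling pipeline for subject-by-feature
tables with many more features than subjects, of the kind produced by
multimodal neuroimaging studies: ROI-level means of eight MRI metrics
(Vol, CT, FD, FW, FA, MD, CBF, CVR) over cortical, subcortical, and
white-matter regions, predicting a cognitive outcome — the baseline total
z-score *Z* or its post-treatment change ΔZ.

## Pipeline

1. **Marginal screening.** Each feature is tested for a patient-vs-control
   mean difference with Welch's unequal-variance t-test; features with
   two-sided p < 0.2 are retained. The threshold is deliberately liberal
   ("soft" screening): it discards features with no marginal group signal
   while keeping weakly associated ones for the joint model. No multiplicity
   correction is applied — screening is a filter, not an inference.
   Screening always uses the full baseline cohort (both groups), even when
   the downstream model is fitted only on patients with follow-up.

2. **Grouped correlation-matrix PCA.** Screened features are grouped (by
   tissue region by default; by metric, or pooled, as options) and each
   group is reduced by PCA on its *sample Pearson correlation matrix*.
   Using the correlation rather than covariance matrix is essential here:
   mean diffusivity lives near 10⁻³ mm²/s while cortical thickness is ~2.6
   mm, and covariance PCA would let one metric's units dominate every
   component. Components are retained by the proportion-of-variance-explained
   (PVE) rule: the smallest k whose cumulative eigenvalue share reaches the
   threshold (0.8 or 0.9). A two-layer variant ("model 1") applies a second,
   global correlation PCA to the concatenated first-layer scores; the
   single-layer variant ("model 2") uses them directly.

3. **AIC stepwise regression.** The retained PC scores enter an ordinary
   least-squares model selected by bidirectional stepwise search under
   AIC = n·ln(SSE/n) + 2(k+1). Cross-validation is avoided on purpose: with
   a few dozen subjects, fold-to-fold variance swamps the model ranking,
   while AIC penalizes complexity analytically.

4. **Equivalent-weight back-propagation.** Every PCA layer is affine, so the
   composite map collapses to scores = X·A + c in closed form. A regression
   ŷ = β̂₀ + Σ_l PC_l β̂_l is therefore *exactly* ŷ = β̃₀ + Σ_j X_j β̃_j with
   β̃ = A·β̂ and β̃₀ = β̂₀ + c·β̂ (stepwise-dropped components contribute zero
   coefficients; loading columns are never removed). Features are ranked by
   the SD-adjusted weights w_j = σ̂_j·β̃_j — the change in predicted outcome
   per one-SD change in feature j — which are invariant under any positive
   rescaling of a feature, unlike the raw β̃_j which inherit arbitrary units.
   Reports keep rows with |w_j| ≥ 0.5 by default. The implementation verifies
   the two prediction routes agree to < 10⁻¹⁰ of the prediction range on
   every fit; this exactness holds only because both the reduction and the
   model are linear.

5. **Model comparison.** Models of the same outcome are ranked by adjusted
   R² = 1 − (SSE/(n−p−1))/(SST/(n−1)). Since SST/(n−1) is shared, adjusted
   R² is a strictly decreasing function of the residual standard error
   RSE = √(SSE/(n−p−1)), and the package asserts the two rankings are exact
   reverses. Alongside the integrative models the suite fits eight
   *unimodality* models (one metric across regions, screened, no PCA) and
   seventeen *modality-region* models (one metric in one region,
   unscreened — small candidate sets need neither screening nor reduction).

## Power and design arithmetic

Cohen's f² = R²/(1−R²) is derived from the **adjusted** R² of a fitted
model and drives the overall multiple-regression F-test power:
power = P(F′(u, n−u−1, λ=f²·n) > F₁₋α(u, n−u−1)) with u covariates.
`required_sample_size` solves the continuous power equation in real n
(degrees of freedom enter the F distributions as reals, as in standard
power software) and rounds to the nearest integer by default; a
conservative ceiling mode is available. For ten covariates, 90% power and
α = 0.05, f² = 0.906 gives n = 33 and f² = 1.731 gives n = 23 — a ~30%
reduction in required sample size for the stronger (integrative) effect.
Complete-case attrition across m modalities compounds as 1 − (1−r)^m:
even 5% per modality over nine data domains loses ≈ 37% of subjects.

## Synthetic cohorts

The generator emulates the study structure: 86 subjects (56 controls, 30
patients, 27 of whom have a follow-up score), the full 147-feature grid
(11 cortical × 7 metrics, 7 subcortical × 7, 7 white-matter × 3), and three
latent factors, one per tissue region. A planted subset of 39 features
(11/23/5 by region, spread across metrics) carries both a standardized
group shift (0.8 within-group SDs) and a loading (0.6) on its region's
factor; remaining features are pure noise (residual SD 0.8 in standardized
units). Six cognitive domain scores are linear in the factors plus noise,
clipped at ±3, and summed to Z; ΔZ is linear in the factors
(loadings 0.7/0.9/0.5 by region, unit noise → oracle R² ≈ 0.61).
Per-metric location/scale families give realistic magnitudes (MD ~ 8·10⁻⁴,
CT ~ 2.6, FD ~ 2.1, CBF ~ 1.2, ...). All draws flow from a single seeded
generator in fixed order, so cohorts are bit-reproducible.

The latent-factor construction (rather than direct feature→outcome
coefficients) is deliberate: outcome information is spread across many
features in several metrics and regions, which is precisely the regime
where integrating modalities should beat any single-metric model — the
qualitative claim the recovery tests check. What the generator does *not*
emulate: spatial correlation beyond the three region factors,
non-Gaussian measurement error, site or scanner effects, and age/sex
structure. Passing recovery tests therefore show the pipeline recovers
this generative structure, not that it would perform identically on real
cohorts.

`oracle_r2` returns the population R² of the best linear predictor of the
outcome from the latent factors — closed form for ΔZ (no clipping), seeded
Monte Carlo (n = 200 000, error O(10⁻²)) for Z where domain clipping makes
moments non-Gaussian. Model adjusted R² converges toward (slightly below)
this value as n grows: the feature-attainable R² is reduced by the finite
reliability with which features recover the factors.

## Numerical choices

- SDs use the n−1 denominator everywhere (standardization, σ̂_j, Welch).
- Eigenvector signs are fixed by orienting each loading column so its
  largest-magnitude entry is positive (ties to the lowest index);
  predictions and adjusted weights are invariant to this choice.
- Eigenvalues below 10⁻¹² are treated as zero: never retained, but kept in
  the PVE denominator via the exact trace; with n−1 < p the PVE rule
  operates on the ≤ n−1 positive eigenvalues.
- The second PCA layer also uses the correlation matrix — first-layer
  scores have unequal variances λ, so standardization is material.
- Stepwise search starts from the full model when it is estimable
  (candidates ≤ n−2) and otherwise from the empty model; the choice is
  recorded in the report. Ties within 10⁻¹⁰ of AIC prefer deletion over
  addition, then the lowest candidate index. Inside the search, subsets
  are scored from precomputed cross-products (Cholesky solves); the final
  model is refitted by least squares.
- A Welch test on two bitwise-constant samples is degenerate by convention:
  t = 0, p = 1 when the constants agree (never selected), p = 0 when they
  differ. Constancy is detected on raw values, since the variance of a
  constant column can pick up mean-subtraction roundoff.
- Missing data are handled by the complete-case contract: analysis tables
  must be fully finite and validation names the offending subject/feature.

## Open design points, resolved

- First-layer grouping is **by region** by default, with by-metric and
  pooled groupings available as configuration.
- For ΔZ models, the PCA, SDs, and weights are fitted on the patient
  follow-up subset only (the modeling cohort), keeping the predictor
  self-contained; fitting the PCA on all subjects is possible by passing
  that cohort explicitly.
- Adjusted-R² confidence intervals use a subject-resampling percentile
  bootstrap (screening held fixed, PCA and stepwise refitted per
  replicate, B ≥ 200, seeded). Intervals at study-sized n are wide and
  should be read qualitatively.
- Sample-size rounding: the continuous power solution is rounded to the
  nearest integer by default (the convention of common power software);
  `rounding="ceil"` guarantees the returned n itself meets the target.

## Problem sizes used in the test suite

Unit and property tests run on fixtures of 4–40 subjects and 1–12
features. Recovery tests use study-sized cohorts (86 × 147) for
screening sensitivity and model-comparison medians (20 seeds), 300
modeling subjects for weight recovery (20 seeds), and 100 vs 1000
subjects (5 seeds each) for the consistency check. These sizes give the
statistical claims several binomial/Monte-Carlo SDs of slack while
keeping the default test run under a minute.

## Known limitations

- Back-propagated weights are exact only for linear PCA + linear
  regression; any nonlinear stage breaks the equivalence.
- Stepwise AIC returns a local optimum; it is checked against exhaustive
  search on small candidate sets, but with many correlated PCs the global
  AIC minimum is not guaranteed.
- At the study's ΔZ sample size (n = 27) the selected models can be
  near-saturated and adjusted R² optimistic; the bootstrap intervals make
  that uncertainty visible rather than removing it.
- The screening threshold, PVE levels, and |w| ≥ 0.5 reporting cut are
  study conventions, not optimized quantities.
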