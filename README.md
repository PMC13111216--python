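# mmpcr — multimodal principal-component regression with exact weight back-propagation

`mmpcr` is a toolkit for modelling "large p, small n" subject-by-feature
tables — built for multimodal neuroimaging studies where each subject
contributes ROI-level means of several MRI metrics (volume, cortical
thickness, fractal dimensionality, free water, FA, MD, CBF, CVR) across
cortical, subcortical, and white-matter regions, and the goal is an
interpretable linear predictor of a cognitive outcome: the baseline total
z-score *Z*, or its change ΔZ after treatment.

The pipeline is: Welch-t screening at p < 0.2 → per-region PCA on the
sample **correlation** matrix (so metrics with wildly different units
contribute equally), truncated by proportion of variance explained
(PVE = 0.8 or 0.9), optionally with a second global PCA layer →
bidirectional AIC stepwise regression on the retained PC scores. The
core algorithm is **equivalent-weight back-propagation**: because every
PCA layer is affine (scores = XA + c), the fitted PC-space model

> ŷᵢ = β̂₀ + Σₗ PCᵢₗ β̂ₗ  =  β̃₀ + Σⱼ Xᵢⱼ β̃ⱼ,  with β̃ = Aβ̂, β̃₀ = β̂₀ + c·β̂

is *exactly* a linear model in the original features. Features are ranked
by the SD-adjusted weights **wⱼ = σ̂ⱼ·β̃ⱼ** — the change in predicted
outcome per one-SD change in feature j, invariant to feature rescaling —
with |wⱼ| ≥ 0.5 as the default reporting cut. The package also fits
single-metric ("unimodality") and metric×region suites for comparison by
adjusted R², a noncentral-F power/design module (Cohen's f² = R²/(1−R²)),
and a seeded synthetic-cohort generator with known ground truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a study-shaped cohort (86 subjects — 56 controls, 30 patients,
27 with follow-up — and the full 147-feature grid), then fit the
single-layer integrative model for baseline *Z* and report the ranked
feature weights:

```sh
mmpcr simulate --seed 7 --out-dir cohort
mmpcr weights --features cohort/features.csv --outcomes cohort/outcomes.csv \
      --model model2 --outcome z --pve 0.9 --w-min 0.5 --out-dir fit
head -7 fit/weights.csv
```

```
feature_id,adjusted_weight,unadjusted_weight,mean,sd,screened_out
Hippo.MD.sub,-0.889647,-11305,0.000800248,7.86948e-05,False
STG.MD.cor,0.708187,7320.04,0.000803396,9.67464e-05,False
Hippo.FD.sub,0.630224,11.1894,2.11563,0.0563231,False
GCC.FW.wm,-0.600548,-30.0796,0.0997661,0.0199653,False
TMP.CT.cor,0.555084,3.75388,2.62104,0.147869,False
PUC.FD.cor,0.523808,12.6565,2.09711,0.0413865,False
```

Each row is one imaging feature (`ROI.metric.region`). The unadjusted
coefficients β̃ⱼ span five orders of magnitude because they inherit each
metric's units (mean diffusivity ~10⁻³ vs cortical thickness ~2.6); the
adjusted weights are directly comparable: one SD more hippocampal MD
lowers the predicted cognitive score by 0.89 points in this fit. The run's
audit JSON records adjusted R² = 0.5802 and a PC-space vs feature-space
prediction gap of 3.6·10⁻¹⁴ — the back-propagated model reproduces the PC
regression to machine precision.

Power/design arithmetic from the command line:

```sh
$ mmpcr power --adj-r2 0.6339 --covariates 10 --power 0.9 --alpha 0.05
f2 = 1.731
required n = 23 (u = 10, power >= 0.9, alpha = 0.05)
power at n = 0.9021

$ mmpcr attrition --rate 0.05 --modalities 9
cumulative loss = 0.3698 (37.0%)
```

With the weaker effect f² = 0.906 (from adjusted R² = 0.4753) the same
design needs n = 33 — the stronger integrative model cuts the required
sample by ~30%. The attrition line shows why multimodal designs need
complete-case planning: 5% loss per modality across nine data domains
removes more than a third of subjects.

Other subcommands: `screen` (per-feature Welch report), `fit` (model
report JSON + weight CSV + suite comparison), `compare` (merge and
re-rank comparison tables). All outputs are deterministic given inputs,
options, and seed, and carry a hash of the run configuration.

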