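"""Named analysis pipelines and model comparison.

Three families of regressions for a cognitive outcome (baseline total
z-score Z over the full cohort, or the treatment change score dZ over
patients with follow-up):

* multimodality models — Welch screening, grouped correlation-PCA
  (single-layer "model2" or with a global second layer "model1"),
  AIC stepwise regression on the retained PC scores, and exact weight
  back-propagation to the feature space;
* unimodality models — one model per imaging metric, screened raw
  features, stepwise AIC, no PCA;
* modality-region models — one model per (metric, region) cell of the
  feature grid (17 cells), unscreened raw features, stepwise AIC.

Screening always uses the full baseline cohort (both groups), even when
the downstream model is fitted on the patient follow-up subset; PCA,
regression, SDs and weights use only the modeling cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .feature_model import (
    METRICS,
    REGION_METRICS,
    REGIONS,
    CohortOutcomes,
    FeatureTable,
)
from .pca_stack import PCAStack, fit_stack
from .regression import FitMetrics, RegressionFit, fit_metrics, stepwise_aic
from .screening import screen_features
from .weight_backprop import EquivalentWeights, backpropagate_weights, verify_equivalence

__all__ = [
    "ModelSpec",
    "ModelReport",
    "run_multimodal",
    "run_unimodality_suite",
    "run_modality_region_suite",
    "compare_models",
    "bootstrap_adj_r2_ci",
]

VARIANTS = ("model1", "model2", "unimodality", "modality_region")


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one named analysis."""

    variant: str
    outcome: str = "deltaZ"  # "Z" or "deltaZ"
    pve: float = 0.9  # multimodality variants only
    metric: str | None = None  # unimodality / modality_region
    region: str | None = None  # modality_region
    grouping: str = "by_region"
    apply_screening: bool | None = None  # None = variant default
    screen_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant in ("model1", "model2") and not 0.0 < self.pve <= 1.0:
            raise ValueError(f"pve must be in (0, 1], got {self.pve}")
        if self.variant in ("unimodality", "modality_region") and self.metric is None:
            raise ValueError(f"{self.variant} requires a metric")
        if self.variant == "modality_region" and self.region is None:
            raise ValueError("modality_region requires a region")

    @property
    def screening_on(self) -> bool:
        if self.apply_screening is not None:
            return self.apply_screening
        # modality-region cells are small enough to skip the HIV-status screen
        return self.variant != "modality_region"

    @property
    def name(self) -> str:
        if self.variant in ("model1", "model2"):
            return f"{self.variant}_pve{self.pve:g}_{self.outcome}"
        if self.variant == "unimodality":
            return f"unimodality_{self.metric}_{self.outcome}"
        return f"modality_region_{self.metric}_{self.region}_{self.outcome}"


@dataclass
class ModelReport:
    """Everything one fitted analysis produced."""

    spec: ModelSpec
    feature_ids: list[str]  # candidates that entered the model stage
    fit: RegressionFit
    metrics: FitMetrics
    outcome_values: pd.Series = field(repr=False)
    screening: pd.DataFrame | None = field(default=None, repr=False)
    stack: PCAStack | None = field(default=None, repr=False)
    weights: EquivalentWeights | None = field(default=None, repr=False)
    equivalence_gap: float | None = None
    stepwise_start: str = "full"

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def adj_r2(self) -> float:
        return self.metrics.adj_r2

    @property
    def no_informative_features(self) -> bool:
        """Stepwise returned the intercept-only model."""
        return self.fit.k == 0

    def stack_summary(self) -> dict[str, int] | None:
        return self.stack.group_summary() if self.stack is not None else None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "variant": self.spec.variant,
            "outcome": self.spec.outcome,
            "n": self.metrics.n,
            "candidates": self.fit.candidate_ids,
            "retained": self.fit.term_ids,
            "intercept": self.fit.beta0_hat,
            "coefficients": self.fit.coefficients(),
            "aic": self.fit.aic,
            "aic_trace": self.fit.aic_trace,
            "adj_r2": self.metrics.adj_r2,
            "rse": self.metrics.rse,
            "pearson_r": self.metrics.pearson_r,
            "pearson_p": self.metrics.pearson_p,
            "stack_summary": self.stack_summary(),
            "equivalence_gap": self.equivalence_gap,
            "stepwise_start": self.stepwise_start,
            "no_informative_features": self.no_informative_features,
        }


def _modeling_ids(table: FeatureTable, outcomes: CohortOutcomes, outcome: str) -> list[str]:
    if outcome == "Z":
        ids = [s for s in table.subject_ids if s in set(outcomes.subject_ids)]
    else:
        keep = set(outcomes.pwh_followup_ids())
        ids = [s for s in table.subject_ids if s in keep]
    if len(ids) < 3:
        raise ValueError(f"modeling cohort has {len(ids)} subjects; need >= 3")
    return ids


def _stepwise_on(
    design: np.ndarray, y: np.ndarray, labels: list[str]
) -> tuple[RegressionFit, str]:
    """Full-start stepwise, falling back to a null start when the full
    model is not estimable (more candidates than residual df allow)."""
    n = len(y)
    start = "full" if len(labels) <= n - 2 else "null"
    return stepwise_aic(design, y, candidate_ids=labels, start=start), start


def run_multimodal(
    table: FeatureTable,
    outcomes: CohortOutcomes,
    spec: ModelSpec,
    covariates: pd.DataFrame | None = None,
) -> ModelReport:
    """Screen → grouped correlation-PCA → stepwise AIC → back-propagation.

    ``covariates`` (indexed by subject id) bypass PCA and join the
    stepwise candidate set directly; their coefficients stay in PC-space
    reporting and do not enter the feature-space weights.
    """
    if spec.variant not in ("model1", "model2"):
        raise ValueError(f"run_multimodal needs model1/model2, got {spec.variant!r}")
    model_ids = _modeling_ids(table, outcomes, spec.outcome)

    screening = None
    candidate_features = table.feature_ids
    if spec.screening_on:
        screening = screen_features(table, outcomes, spec.screen_threshold)
        candidate_features = screening.loc[screening["selected"], "feature_id"].tolist()
        if not candidate_features:
            raise ValueError("screening selected no features")

    modeling = table.select_subjects(model_ids).select_features(candidate_features)
    stack = fit_stack(
        modeling,
        grouping=spec.grouping,
        pve=spec.pve,
        two_layer=(spec.variant == "model1"),
    )
    scores = stack.transform(modeling.values)
    labels = list(stack.score_labels)
    design = scores
    if covariates is not None:
        cov = covariates.loc[model_ids]
        design = np.column_stack([scores, cov.to_numpy(dtype=float)])
        labels = labels + [f"cov.{c}" for c in cov.columns]

    y = outcomes.outcome_vector(spec.outcome).loc[model_ids].to_numpy(dtype=float)
    fit, start = _stepwise_on(design, y, labels)
    yhat = fit.predict(design, labels)
    metrics = fit_metrics(y, yhat, p_used=fit.k)

    # Weights back-propagate only the PC part of the model; any retained
    # covariates contribute identically to both prediction routes.
    pc_terms = [t for t in fit.term_ids if t in stack.score_labels]
    pc_fit = RegressionFit(
        term_ids=pc_terms,
        beta0_hat=fit.beta0_hat,
        beta_hat=np.array([fit.coefficients()[t] for t in pc_terms]),
        n=fit.n,
        sse=fit.sse,
        aic=fit.aic,
        candidate_ids=stack.score_labels,
    )
    weights = backpropagate_weights(stack, pc_fit, full_feature_ids=table.feature_ids)
    gap, _ = verify_equivalence(modeling, stack, pc_fit, weights)

    return ModelReport(
        spec=spec,
        feature_ids=candidate_features,
        fit=fit,
        metrics=metrics,
        outcome_values=pd.Series(y, index=model_ids),
        screening=screening,
        stack=stack,
        weights=weights,
        equivalence_gap=gap,
        stepwise_start=start,
    )


def _run_raw_feature_model(
    table: FeatureTable,
    outcomes: CohortOutcomes,
    spec: ModelSpec,
    candidate_features: list[str],
    screening: pd.DataFrame | None,
) -> ModelReport:
    """Stepwise AIC directly on raw features (no PCA)."""
    model_ids = _modeling_ids(table, outcomes, spec.outcome)
    y = outcomes.outcome_vector(spec.outcome).loc[model_ids].to_numpy(dtype=float)
    if candidate_features:
        modeling = table.select_subjects(model_ids).select_features(candidate_features)
        fit, start = _stepwise_on(modeling.values, y, candidate_features)
        yhat = fit.predict(modeling.values, candidate_features)
    else:  # no candidates survived: intercept-only by construction
        fit, start = _stepwise_on(np.empty((len(y), 0)), y, [])
        yhat = fit.predict(np.empty((len(y), 0)), [])
    metrics = fit_metrics(y, yhat, p_used=fit.k)
    return ModelReport(
        spec=spec,
        feature_ids=candidate_features,
        fit=fit,
        metrics=metrics,
        outcome_values=pd.Series(y, index=model_ids),
        screening=screening,
        stepwise_start=start,
    )


def run_unimodality_suite(
    table: FeatureTable,
    outcomes: CohortOutcomes,
    metrics: Iterable[str] = METRICS,
    outcome: str = "deltaZ",
    screen_threshold: float = 0.2,
) -> list[ModelReport]:
    """One screened, PCA-free stepwise model per imaging metric (8 by default).

    A metric whose screened candidate set is empty, or whose stepwise
    search keeps nothing, is reported as a no-informative-features model
    rather than raised.
    """
    screening = screen_features(table, outcomes, screen_threshold)
    selected = set(screening.loc[screening["selected"], "feature_id"])
    reports = []
    for metric in metrics:
        spec = ModelSpec(variant="unimodality", outcome=outcome, metric=metric,
                         screen_threshold=screen_threshold)
        cand = [
            d.feature_id
            for d in table.descriptors
            if d.metric == metric and d.feature_id in selected
        ]
        reports.append(_run_raw_feature_model(table, outcomes, spec, cand, screening))
    return reports


def run_modality_region_suite(
    table: FeatureTable,
    outcomes: CohortOutcomes,
    outcome: str = "deltaZ",
) -> list[ModelReport]:
    """One unscreened stepwise model per (metric, region) grid cell.

    The full grid has 7 cortical + 7 subcortical + 3 white-matter cells
    = 17 models; cells absent from the table are skipped.
    """
    reports = []
    for region in REGIONS:
        for metric in REGION_METRICS[region]:
            cand = [
                d.feature_id
                for d in table.descriptors
                if d.metric == metric and d.region == region
            ]
            if not cand:
                continue
            spec = ModelSpec(
                variant="modality_region", outcome=outcome, metric=metric, region=region
            )
            reports.append(_run_raw_feature_model(table, outcomes, spec, cand, None))
    return reports


def compare_models(reports: list[ModelReport]) -> pd.DataFrame:
    """Rank models of the same outcome by adjusted R² (descending).

    Since every model fits the same outcome vector, SST/(n−1) is shared
    and adjusted R² is a strictly decreasing function of RSE — the RSE
    ordering must be the exact reverse, which is asserted.
    """
    if not reports:
        raise ValueError("no reports to compare")
    ref = reports[0].outcome_values
    for r in reports[1:]:
        if not ref.equals(r.outcome_values):
            raise ValueError(
                f"cannot compare models of different outcomes "
                f"({reports[0].name} vs {r.name})"
            )
    df = pd.DataFrame(
        {
            "model": [r.name for r in reports],
            "adj_r2": [r.metrics.adj_r2 for r in reports],
            "rse": [r.metrics.rse for r in reports],
            "n": [r.metrics.n for r in reports],
            "p_used": [r.metrics.p_used for r in reports],
            "aic": [r.fit.aic for r in reports],
            "no_informative_features": [r.no_informative_features for r in reports],
        }
    )
    df = df.sort_values(["adj_r2", "model"], ascending=[False, True]).reset_index(drop=True)
    by_rse = df.sort_values(["rse", "model"], ascending=[True, True]).reset_index(drop=True)
    if not (df["model"] == by_rse["model"]).all():  # pragma: no cover - invariant
        raise AssertionError("adjusted-R² and RSE rankings disagree")
    return df


def bootstrap_adj_r2_ci(
    table: FeatureTable,
    outcomes: CohortOutcomes,
    spec: ModelSpec,
    B: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Percentile bootstrap interval for a multimodality model's adjusted R².

    Subjects of the modeling cohort are resampled with replacement;
    the PCA stack and stepwise selection are refitted per replicate while
    the screening decision is held fixed at the original cohort's.
    Replicates with a degenerate design (e.g. a constant resampled
    feature) are skipped and counted.  Fully reproducible given ``seed``.
    """
    if B < 200:
        raise ValueError(f"need B >= 200 replicates, got {B}")
    rng = np.random.default_rng(seed)
    base = run_multimodal(table, outcomes, spec)
    model_ids = base.outcome_values.index.tolist()
    modeling = table.select_subjects(model_ids).select_features(base.feature_ids)
    Xdf = modeling.to_frame()
    y = base.outcome_values.to_numpy()
    n = len(model_ids)

    stats_: list[float] = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        rep = Xdf.iloc[idx].copy()
        rep.index = pd.Index([f"b{t}" for t in range(n)], name="subject_id")
        try:
            rep_table = FeatureTable(rep, modeling.descriptors)
            stack = fit_stack(
                rep_table,
                grouping=spec.grouping,
                pve=spec.pve,
                two_layer=(spec.variant == "model1"),
            )
            scores = stack.transform(rep_table.values)
            fit, _ = _stepwise_on(scores, y[idx], list(stack.score_labels))
            yhat = fit.predict(scores, list(stack.score_labels))
            stats_.append(fit_metrics(y[idx], yhat, p_used=fit.k).adj_r2)
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
    if not stats_:
        raise RuntimeError("all bootstrap replicates were degenerate")
    alpha = 1.0 - level
    lo, hi = np.quantile(stats_, [alpha / 2, 1 - alpha / 2])
    return {
        "estimate": base.metrics.adj_r2,
        "lower": float(lo),
        "upper": float(hi),
        "level": level,
        "B": B,
        "skipped": skipped,
    }
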