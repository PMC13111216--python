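"""Exact equivalent-weight back-propagation from PC space to feature space.

A regression fitted on principal-component scores predicts
ŷ_i = β̂₀ + Σ_l PC_il β̂_l.  Because every PCA layer is affine in the
original features (scores = X·A + c), the same predictions can be
written exactly as ŷ_i = β̃₀ + Σ_j X_ij β̃_j with

    β̃ = A·β̂        β̃₀ = β̂₀ + c·β̂

where β̂ spans ALL stack scores, with zeros for components dropped by
stepwise selection.  The raw coefficients β̃_j inherit each feature's
arbitrary units, so features are ranked by the SD-adjusted weights
w_j = σ̂_j·β̃_j — the change in predicted outcome per one-SD change in
feature j, invariant under any positive rescaling of that feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_model import FeatureTable
from .pca_stack import PCAStack, stack_affine_map
from .regression import RegressionFit

__all__ = [
    "EquivalentWeights",
    "backpropagate_weights",
    "rank_and_select",
    "verify_equivalence",
]

DEFAULT_W_MIN = 0.5


@dataclass
class EquivalentWeights:
    """Feature-space coefficients equivalent to a PC-space regression."""

    feature_ids: list[str]
    beta0_tilde: float
    beta_tilde: np.ndarray  # unadjusted weights β̃_j
    sigma_hat: np.ndarray  # training-sample SDs σ̂_j (ddof=1)
    mean: np.ndarray  # training-sample means
    adjusted: np.ndarray = field(init=False)  # w_j = σ̂_j · β̃_j
    screened_out: np.ndarray | None = None  # True where screening removed j

    def __post_init__(self) -> None:
        self.adjusted = self.sigma_hat * self.beta_tilde
        if self.screened_out is None:
            self.screened_out = np.zeros(len(self.feature_ids), dtype=bool)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Feature-space predictions β̃₀ + X·β̃."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.beta0_tilde + X @ self.beta_tilde

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "adjusted_weight": self.adjusted,
                "unadjusted_weight": self.beta_tilde,
                "mean": self.mean,
                "sd": self.sigma_hat,
                "screened_out": self.screened_out,
            }
        )


def backpropagate_weights(
    stack: PCAStack,
    fit: RegressionFit,
    full_feature_ids: list[str] | None = None,
    screened_out_ids: list[str] | None = None,
) -> EquivalentWeights:
    """Map PC-space coefficients back to an equivalent feature-space model.

    ``fit``'s retained terms must be a subset of the stack's score
    labels; stepwise-dropped components contribute zero coefficients.
    SDs and means are the stack's training statistics, reassembled from
    its first-layer standardization.  When ``full_feature_ids`` is
    given, features outside the stack (removed at screening) appear
    with zero weight and a ``screened_out`` flag so reports can span
    the whole feature grid.
    """
    labels = stack.score_labels
    unknown = [t for t in fit.term_ids if t not in labels]
    if unknown:
        raise KeyError(f"fit terms not among stack scores: {unknown}")
    beta = np.zeros(len(labels))
    for term, b in zip(fit.term_ids, fit.beta_hat):
        beta[labels.index(term)] = b

    A, c = stack_affine_map(stack)
    beta_tilde = A @ beta
    beta0_tilde = fit.beta0_hat + float(c @ beta)

    # Training-sample moments, per original column position.
    p = len(stack.feature_ids)
    mu = np.empty(p)
    sigma = np.empty(p)
    for layer, idx in zip(stack.layer1, stack.column_partition):
        mu[np.asarray(idx)] = layer.mu
        sigma[np.asarray(idx)] = layer.sigma

    if full_feature_ids is None:
        return EquivalentWeights(
            feature_ids=list(stack.feature_ids),
            beta0_tilde=beta0_tilde,
            beta_tilde=beta_tilde,
            sigma_hat=sigma,
            mean=mu,
        )

    # Embed into the full grid with zeros for screened-out features.
    pos = {f: j for j, f in enumerate(stack.feature_ids)}
    pf = len(full_feature_ids)
    bt = np.zeros(pf)
    sd = np.zeros(pf)
    mn = np.full(pf, np.nan)
    out = np.ones(pf, dtype=bool)
    for jf, f in enumerate(full_feature_ids):
        if f in pos:
            j = pos[f]
            bt[jf], sd[jf], mn[jf], out[jf] = beta_tilde[j], sigma[j], mu[j], False
    if screened_out_ids is not None:
        expected = set(full_feature_ids) - set(stack.feature_ids)
        if expected != set(screened_out_ids):
            raise ValueError("screened_out_ids inconsistent with stack features")
    mn = np.where(out, 0.0, mn)
    return EquivalentWeights(
        feature_ids=list(full_feature_ids),
        beta0_tilde=beta0_tilde,
        beta_tilde=bt,
        sigma_hat=sd,
        mean=mn,
        screened_out=out,
    )


def rank_and_select(
    weights: EquivalentWeights | pd.DataFrame, w_min: float = DEFAULT_W_MIN
) -> pd.DataFrame:
    """Rank features by |adjusted weight| and keep rows with |w| >= w_min.

    Ties in |w| break by feature id, lexicographically.  Accepts either
    an :class:`EquivalentWeights` or an already-built report frame with
    the same columns.
    """
    df = weights.to_frame() if isinstance(weights, EquivalentWeights) else weights.copy()
    df = df[np.abs(df["adjusted_weight"]) >= w_min]
    df = df.sort_values(
        ["adjusted_weight", "feature_id"],
        key=lambda s: -s.abs() if s.name == "adjusted_weight" else s,
    ).reset_index(drop=True)
    cols = ["feature_id", "adjusted_weight", "unadjusted_weight", "mean", "sd"]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]


def verify_equivalence(
    table: FeatureTable,
    stack: PCAStack,
    fit: RegressionFit,
    weights: EquivalentWeights,
    rel_tol: float = 1e-10,
) -> tuple[float, bool]:
    """Max |PC-space prediction − feature-space prediction| over subjects.

    The defining property of the back-propagation: the two evaluation
    routes agree to numerical precision.  Returns (gap, passed) where
    ``passed`` compares the gap against ``rel_tol`` times the prediction
    range (or 1 if the predictions are constant).
    """
    X = table.select_features(stack.feature_ids).values
    scores = stack.transform(X)
    yhat_pc = fit.predict(scores, stack.score_labels)
    pos = {f: j for j, f in enumerate(weights.feature_ids)}
    cols = [pos[f] for f in stack.feature_ids]
    # feature-space route over the stack's own columns (screened-out are zero)
    Xfull = np.zeros((X.shape[0], len(weights.feature_ids)))
    Xfull[:, cols] = X
    yhat_feat = weights.predict(Xfull)
    gap = float(np.max(np.abs(yhat_pc - yhat_feat)))
    scale = float(np.ptp(yhat_pc)) or 1.0
    return gap, gap < rel_tol * scale
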