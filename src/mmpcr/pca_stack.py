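"""Layered correlation-matrix PCA with an exact composite affine map.

Features are grouped (by tissue region, by metric, or pooled) and each
group is reduced by PCA on its sample Pearson correlation matrix — not
the covariance matrix — so that metrics measured on wildly different
natural scales (mean diffusivity ~1e-3, cortical thickness ~2.6 mm)
contribute on equal footing.  Components are retained by a cumulative
proportion-of-variance-explained (PVE) rule.

A stack is either single-layer (per-group PCAs whose scores are the
final features; "Model 2") or two-layer (a second, global correlation
PCA over the concatenated first-layer scores; "Model 1").  Because every
step is affine, the whole stack collapses to one exact map
``scores = X @ A + c``; that closed form is what makes downstream weight
back-propagation exact rather than approximate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .feature_model import METRICS, REGIONS, FeatureTable

__all__ = [
    "PCALayer",
    "PCAStack",
    "fit_correlation_pca",
    "pca_transform",
    "fit_stack",
    "stack_affine_map",
]

#: Eigenvalues below this are treated as numerically zero (never retained).
ZERO_EIGENVALUE_TOL = 1e-12

GROUPINGS = ("by_region", "by_metric", "single_group")


@dataclass
class PCALayer:
    """One fitted correlation-PCA: standardization + retained eigenvectors."""

    group_key: str
    input_labels: list[str]
    mu: np.ndarray  # per-input training means
    sigma: np.ndarray  # per-input training SDs (ddof=1)
    loadings: np.ndarray  # all eigenvectors, columns, eigenvalue-descending
    eigenvalues: np.ndarray  # sorted descending; sums to n_inputs (trace)
    k_retained: int
    pve_threshold: float

    @property
    def n_inputs(self) -> int:
        return len(self.input_labels)

    @property
    def score_labels(self) -> list[str]:
        return [f"{self.group_key}.PC{l + 1}" for l in range(self.k_retained)]

    @property
    def retained_loadings(self) -> np.ndarray:
        return self.loadings[:, : self.k_retained]


def _orient_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector orientation.

    Each column is flipped so that its largest-magnitude entry is
    positive; ties resolve to the lowest input index (argmax order).
    PCA is otherwise defined only up to column signs, and different
    linear-algebra backends make different choices.
    """
    V = V.copy()
    idx = np.argmax(np.abs(V), axis=0)
    flip = V[idx, np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    return V


def fit_correlation_pca(
    X: np.ndarray,
    pve: float,
    group_key: str = "all",
    input_labels: list[str] | None = None,
) -> PCALayer:
    """Eigendecompose the sample Pearson correlation matrix of X.

    Columns are standardized by their training mean and SD (n−1
    denominator); eigenvalues are sorted descending and the smallest
    number of components whose cumulative share of the trace reaches
    ``pve`` is retained.  Numerically zero eigenvalues stay in the PVE
    denominator (the trace is exact) but can never be retained, so with
    n−1 < p the rule operates on the at most n−1 positive eigenvalues.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need n >= 3 subjects, got {n}")
    if not 0.0 < pve <= 1.0:
        raise ValueError(f"pve must be in (0, 1], got {pve}")
    if input_labels is None:
        input_labels = [f"x{j}" for j in range(p)]
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sigma == 0.0)
    if dead.size:
        raise ValueError(
            f"constant column(s) cannot be standardized: "
            f"{[input_labels[j] for j in dead]}"
        )
    Z = (X - mu) / sigma
    R = (Z.T @ Z) / (n - 1)
    R = (R + R.T) / 2.0  # enforce exact symmetry before eigh
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _orient_signs(evecs[:, order])

    trace = float(evals.sum())
    positive = int(np.sum(evals >= ZERO_EIGENVALUE_TOL))
    cum = np.cumsum(evals) / trace
    k = int(np.searchsorted(cum, pve - 1e-12) + 1)
    k = min(max(k, 1), positive)
    return PCALayer(
        group_key=group_key,
        input_labels=list(input_labels),
        mu=mu,
        sigma=sigma,
        loadings=evecs,
        eigenvalues=evals,
        k_retained=k,
        pve_threshold=pve,
    )


def pca_transform(layer: PCALayer, X: np.ndarray) -> np.ndarray:
    """Project rows of X onto the layer's retained components."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != layer.n_inputs:
        raise ValueError(
            f"expected {layer.n_inputs} columns (training order), got {X.shape[1]}"
        )
    return ((X - layer.mu) / layer.sigma) @ layer.retained_loadings


def _group_columns(table: FeatureTable, grouping: str) -> list[tuple[str, list[int]]]:
    """Partition table columns into ordered (group_key, column indices)."""
    if grouping == "single_group":
        return [("all", list(range(table.n_features)))]
    if grouping == "by_region":
        keys = REGIONS
        attr = "region"
    elif grouping == "by_metric":
        keys = METRICS
        attr = "metric"
    else:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    out = []
    for key in keys:
        idx = [j for j, d in enumerate(table.descriptors) if getattr(d, attr) == key]
        if idx:
            out.append((key, idx))
    return out


@dataclass
class PCAStack:
    """A fitted one- or two-layer correlation-PCA transform."""

    feature_ids: list[str]
    grouping: str
    pve: float
    two_layer: bool
    layer1: list[PCALayer]
    layer2: PCALayer | None
    affine_A: np.ndarray = field(repr=False)  # p x L
    affine_c: np.ndarray = field(repr=False)  # L
    score_labels: list[str] = field(default_factory=list)
    #: original-table column indices feeding each first-layer group
    column_partition: list[list[int]] = field(default_factory=list, repr=False)

    @property
    def final_dim(self) -> int:
        return len(self.score_labels)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Final scores via the cached affine map (exact, closed form)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"expected {len(self.feature_ids)} feature columns, got {X.shape[1]}"
            )
        return X @ self.affine_A + self.affine_c

    def transform_sequential(self, X: np.ndarray) -> np.ndarray:
        """Final scores by applying each fitted layer in turn.

        Mathematically identical to :meth:`transform`; kept as an
        explicit second evaluation path for equivalence audits.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        parts = [
            pca_transform(layer, X[:, idx])
            for layer, idx in zip(self.layer1, self.column_partition)
        ]
        scores = np.hstack(parts)
        if self.layer2 is not None:
            scores = pca_transform(self.layer2, scores)
        return scores

    def group_summary(self) -> dict[str, int]:
        """Retained component count per first-layer group (and 'global')."""
        out = {layer.group_key: layer.k_retained for layer in self.layer1}
        if self.layer2 is not None:
            out["global"] = self.layer2.k_retained
        return out

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        def layer_dict(layer: PCALayer) -> dict:
            return {
                "group_key": layer.group_key,
                "input_labels": layer.input_labels,
                "mu": layer.mu.tolist(),
                "sigma": layer.sigma.tolist(),
                "loadings": layer.loadings.tolist(),
                "eigenvalues": layer.eigenvalues.tolist(),
                "k_retained": layer.k_retained,
                "pve_threshold": layer.pve_threshold,
            }

        doc = {
            "feature_ids": self.feature_ids,
            "grouping": self.grouping,
            "pve": self.pve,
            "two_layer": self.two_layer,
            "layer1": [layer_dict(l) for l in self.layer1],
            "layer2": layer_dict(self.layer2) if self.layer2 is not None else None,
            "affine_A": self.affine_A.tolist(),
            "affine_c": self.affine_c.tolist(),
            "score_labels": self.score_labels,
            "column_partition": self.column_partition,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "PCAStack":
        doc = json.loads(text)

        def mk_layer(d: dict | None) -> PCALayer | None:
            if d is None:
                return None
            return PCALayer(
                group_key=d["group_key"],
                input_labels=d["input_labels"],
                mu=np.asarray(d["mu"]),
                sigma=np.asarray(d["sigma"]),
                loadings=np.asarray(d["loadings"]),
                eigenvalues=np.asarray(d["eigenvalues"]),
                k_retained=d["k_retained"],
                pve_threshold=d["pve_threshold"],
            )

        return cls(
            feature_ids=doc["feature_ids"],
            grouping=doc["grouping"],
            pve=doc["pve"],
            two_layer=doc["two_layer"],
            layer1=[mk_layer(d) for d in doc["layer1"]],
            layer2=mk_layer(doc["layer2"]),
            affine_A=np.asarray(doc["affine_A"]),
            affine_c=np.asarray(doc["affine_c"]),
            score_labels=doc["score_labels"],
            column_partition=doc["column_partition"],
        )


def fit_stack(
    table: FeatureTable,
    grouping: str = "by_region",
    pve: float = 0.9,
    two_layer: bool = False,
) -> PCAStack:
    """Fit per-group correlation PCAs and (optionally) a global second layer.

    The first layer fits one correlation PCA per feature group; their
    retained scores are concatenated in group order.  With
    ``two_layer=True`` a second correlation PCA of those scores yields
    the final features (the first-layer scores have unequal variances
    λ, so standardizing again is material).  The composite feature→score
    affine map is computed in closed form and cached.
    """
    groups = _group_columns(table, grouping)
    X = table.values
    p = table.n_features

    # Layer 1: one PCA per group; block-diagonal affine map assembled in
    # original column positions.
    layers: list[PCALayer] = []
    blocks_A: list[tuple[list[int], np.ndarray]] = []
    c_parts: list[np.ndarray] = []
    for key, idx in groups:
        labels = [table.feature_ids[j] for j in idx]
        layer = fit_correlation_pca(X[:, idx], pve, group_key=key, input_labels=labels)
        layers.append(layer)
        Vk = layer.retained_loadings
        blocks_A.append((idx, Vk / layer.sigma[:, None]))
        c_parts.append(-(layer.mu / layer.sigma) @ Vk)

    L1 = sum(layer.k_retained for layer in layers)
    A1 = np.zeros((p, L1))
    offset = 0
    for idx, block in blocks_A:
        A1[np.asarray(idx), offset : offset + block.shape[1]] = block
        offset += block.shape[1]
    c1 = np.concatenate(c_parts)
    labels1 = [lab for layer in layers for lab in layer.score_labels]

    layer2: PCALayer | None = None
    if two_layer:
        scores1 = X @ A1 + c1
        layer2 = fit_correlation_pca(scores1, pve, group_key="global", input_labels=labels1)
        Vk2 = layer2.retained_loadings
        A = A1 @ (Vk2 / layer2.sigma[:, None])
        c = ((c1 - layer2.mu) / layer2.sigma) @ Vk2
        score_labels = layer2.score_labels
    else:
        A, c, score_labels = A1, c1, labels1

    stack = PCAStack(
        feature_ids=list(table.feature_ids),
        grouping=grouping,
        pve=pve,
        two_layer=two_layer,
        layer1=layers,
        layer2=layer2,
        affine_A=A,
        affine_c=c,
        score_labels=score_labels,
        column_partition=[idx for _, idx in groups],
    )
    return stack


def stack_affine_map(stack: PCAStack) -> tuple[np.ndarray, np.ndarray]:
    """The cached exact affine map (A, c) with scores = X @ A + c."""
    return stack.affine_A, stack.affine_c
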