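"""OLS, the AIC criterion, bidirectional stepwise selection, fit metrics.

Model selection for the small-sample regressions in this package is
AIC-based stepwise search rather than cross-validation: with a few dozen
subjects, held-out folds are too unstable to rank models, while AIC
penalizes complexity analytically.  Models fitted to the same outcome
are compared by adjusted R², which is a monotone decreasing function of
the residual standard error and therefore yields the same ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

__all__ = [
    "RegressionFit",
    "FitMetrics",
    "ols_fit",
    "model_aic",
    "stepwise_aic",
    "fit_metrics",
]

#: Two moves whose AICs differ by less than this are tied (tie-break applies).
AIC_TIE_TOL = 1e-10

RANK_TOL = 1e-8


@dataclass
class RegressionFit:
    """A least-squares linear model over a labelled candidate set."""

    term_ids: list[str]  # retained predictors, in candidate order
    beta0_hat: float
    beta_hat: np.ndarray  # one coefficient per retained term
    n: int
    sse: float
    aic: float
    candidate_ids: list[str]
    aic_trace: list[dict] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.term_ids)

    @property
    def residual_df(self) -> int:
        return self.n - self.k - 1

    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.term_ids, self.beta_hat.tolist()))

    def predict(self, design: np.ndarray, column_ids: list[str]) -> np.ndarray:
        """Predict from a design matrix whose columns are labelled."""
        design = np.atleast_2d(np.asarray(design, dtype=float))
        pos = {lab: j for j, lab in enumerate(column_ids)}
        missing = [t for t in self.term_ids if t not in pos]
        if missing:
            raise KeyError(f"design lacks fitted terms: {missing}")
        cols = [pos[t] for t in self.term_ids]
        return self.beta0_hat + design[:, cols] @ self.beta_hat


@dataclass(frozen=True)
class FitMetrics:
    sse: float
    sst: float
    adj_r2: float
    rse: float
    pearson_r: float
    pearson_p: float
    p_used: int
    n: int


def _lstsq_fit(Xd: np.ndarray, y: np.ndarray, labels: list[str]) -> tuple[np.ndarray, float]:
    """Intercept-augmented least squares; errors on rank deficiency."""
    n = len(y)
    M = np.column_stack([np.ones(n), Xd]) if Xd.shape[1] else np.ones((n, 1))
    rank = np.linalg.matrix_rank(M, tol=RANK_TOL * max(M.shape))
    if rank < M.shape[1]:
        # Identify which terms are linearly dependent on their predecessors.
        collinear = []
        for j in range(1, M.shape[1]):
            if np.linalg.matrix_rank(M[:, : j + 1], tol=RANK_TOL * max(M.shape)) <= np.linalg.matrix_rank(
                M[:, :j], tol=RANK_TOL * max(M.shape)
            ):
                collinear.append(labels[j - 1])
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear terms: {collinear or labels}"
        )
    coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ coef
    return coef, float(resid @ resid)


def ols_fit(
    design: np.ndarray,
    y: np.ndarray,
    term_ids: list[str] | None = None,
    candidate_ids: list[str] | None = None,
) -> RegressionFit:
    """Ordinary least squares with an always-included intercept.

    ``design`` holds one column per retained term.  Requires
    n >= k + 2 (at least one residual degree of freedom) and a design of
    full column rank.
    """
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    y = np.asarray(y, dtype=float)
    n, k = design.shape
    if term_ids is None:
        term_ids = [f"x{j}" for j in range(k)]
    if len(term_ids) != k:
        raise ValueError("term_ids length must match design columns")
    if n < k + 2:
        raise ValueError(f"need n >= k + 2 (n={n}, k={k})")
    coef, sse = _lstsq_fit(design, y, list(term_ids))
    fit = RegressionFit(
        term_ids=list(term_ids),
        beta0_hat=float(coef[0]),
        beta_hat=coef[1:],
        n=n,
        sse=sse,
        aic=math.nan,
        candidate_ids=list(candidate_ids) if candidate_ids is not None else list(term_ids),
    )
    fit.aic = model_aic(fit)
    return fit


def model_aic(fit: RegressionFit) -> float:
    """Gaussian-likelihood AIC up to an additive constant.

    AIC = n·ln(SSE/n) + 2·(k+1), with k the retained predictors
    (intercept excluded from k but counted as a parameter).  Only AIC
    differences drive selection, so constant terms are dropped.  A
    perfect fit (SSE = 0) returns −inf: it dominates every alternative.
    """
    if fit.sse <= 0.0:
        return -math.inf
    return fit.n * math.log(fit.sse / fit.n) + 2.0 * (fit.k + 1)


class _GramScorer:
    """SSE/AIC of candidate subsets from precomputed cross-products.

    The stepwise search scores thousands of subset models; only their
    SSE (hence AIC) is needed.  With G = M'M and g = M'y precomputed for
    the intercept-augmented full design M, each subset costs one
    Cholesky solve of its own size instead of a fresh least-squares
    decomposition of the n-row design.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        n = len(y)
        M = np.column_stack([np.ones(n), X])
        self.G = M.T @ M
        self.g = M.T @ y
        self.yy = float(y @ y)
        self.n = n

    def sse_aic(self, subset: tuple[int, ...]) -> tuple[float, float]:
        """(SSE, AIC) of the subset model; LinAlgError if singular."""
        idx = np.concatenate(([0], np.asarray(subset, dtype=int) + 1))
        Gss = self.G[np.ix_(idx, idx)]
        # cho_factor raises LinAlgError on a singular (collinear) subset
        cf = linalg.cho_factor(Gss, lower=True)
        diag = np.abs(np.diag(cf[0]))
        if diag.min() <= RANK_TOL * diag.max():
            raise np.linalg.LinAlgError("near-singular subset")
        coef = linalg.cho_solve(cf, self.g[idx])
        sse = max(self.yy - float(self.g[idx] @ coef), 0.0)
        k = len(subset)
        aic = -math.inf if sse == 0.0 else self.n * math.log(sse / self.n) + 2.0 * (k + 1)
        return sse, aic


def _fit_subset(
    X: np.ndarray, y: np.ndarray, subset: tuple[int, ...], labels: list[str]
) -> RegressionFit:
    fit = ols_fit(
        X[:, list(subset)],
        y,
        term_ids=[labels[j] for j in subset],
        candidate_ids=labels,
    )
    return fit


def stepwise_aic(
    design: np.ndarray,
    y: np.ndarray,
    candidate_ids: list[str] | None = None,
    start: str = "full",
) -> RegressionFit:
    """Bidirectional AIC stepwise selection over a labelled candidate set.

    From the start model (full by default, empty with ``start='null'``),
    every single-term deletion and single-term addition is scored; the
    move with the lowest AIC is taken if it improves on the current
    model, and the search stops at a local optimum: no single add or
    drop lowers AIC.  Ties (within 1e-10) prefer deletion over addition,
    then the lowest candidate index, for determinism and parsimony.
    """
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    y = np.asarray(y, dtype=float)
    n, m = design.shape
    if candidate_ids is None:
        candidate_ids = [f"x{j}" for j in range(m)]
    labels = list(candidate_ids)
    if start not in ("full", "null"):
        raise ValueError(f"start must be 'full' or 'null', got {start!r}")
    if start == "full" and m > n - 2:
        raise ValueError(
            f"full start needs n >= candidates + 2 (n={n}, candidates={m}); "
            "reduce dimension first or use a null start"
        )

    scorer = _GramScorer(design, y)
    current: tuple[int, ...] = tuple(range(m)) if start == "full" else ()
    try:
        _, current_aic = scorer.sse_aic(current)
    except np.linalg.LinAlgError:
        # fall back to the decomposition route, which names the collinear terms
        _fit_subset(design, y, current, labels)
        raise
    trace = [{"move": "start", "term": None, "aic": current_aic, "k": len(current)}]

    max_moves = max(2 * m * m, 4)
    for _ in range(max_moves):
        # moves: (kind_rank, index, new_subset); deletions rank before additions
        moves: list[tuple[int, int, tuple[int, ...]]] = []
        for j in current:
            moves.append((0, j, tuple(t for t in current if t != j)))
        for j in range(m):
            if j not in current and len(current) + 1 <= n - 2:
                moves.append((1, j, tuple(sorted(current + (j,)))))

        best = None
        for kind, j, subset in moves:
            try:
                _, aic = scorer.sse_aic(subset)
            except np.linalg.LinAlgError:
                continue  # collinear candidate subsets are simply unavailable
            if best is None or aic < best[0] - AIC_TIE_TOL or (
                abs(aic - best[0]) <= AIC_TIE_TOL and (kind, j) < (best[1], best[2])
            ):
                best = (aic, kind, j, subset)
        if best is None or best[0] >= current_aic - AIC_TIE_TOL:
            break
        current_aic, kind, j, current = best
        trace.append(
            {
                "move": "drop" if kind == 0 else "add",
                "term": labels[j],
                "aic": current_aic,
                "k": len(current),
            }
        )
    else:  # pragma: no cover - defensive; strict improvement forbids cycles
        raise RuntimeError("stepwise search exceeded its move budget")

    current_fit = _fit_subset(design, y, current, labels)
    current_fit.aic_trace = trace
    current_fit.candidate_ids = labels
    return current_fit


def fit_metrics(y: np.ndarray, y_hat: np.ndarray, p_used: int) -> FitMetrics:
    """Adjusted R², residual standard error, and observed-vs-fitted Pearson r.

    adj R² = 1 − (SSE/(n−p−1)) / (SST/(n−1)); RSE = sqrt(SSE/(n−p−1)).
    The Pearson p-value is two-sided from t = r·sqrt((n−2)/(1−r²)).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    n = len(y)
    if n <= p_used + 1:
        raise ValueError(f"need n > p_used + 1 (n={n}, p_used={p_used})")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("constant outcome: SST = 0")
    sse = float(((y - y_hat) ** 2).sum())
    resid_df = n - p_used - 1
    adj_r2 = 1.0 - (sse / resid_df) / (sst / (n - 1))
    rse = math.sqrt(sse / resid_df)
    if np.std(y_hat) <= 1e-12 * (abs(float(np.mean(y_hat))) + 1.0):
        r, p = 0.0, 1.0  # fitted values constant (intercept-only model)
    else:
        r, p = stats.pearsonr(y, y_hat)
    return FitMetrics(
        sse=sse,
        sst=sst,
        adj_r2=adj_r2,
        rse=rse,
        pearson_r=float(r),
        pearson_p=float(p),
        p_used=p_used,
        n=n,
    )
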