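"""Power and design arithmetic for the overall multiple-regression F-test.

Cohen's f² = R²/(1−R²) converts a model's explained-variance fraction
into the effect size driving the noncentral-F power calculation for a
regression with u covariates: at sample size n the test statistic under
the alternative follows F′(u, n−u−1, λ) with noncentrality λ = f²·n.
Here f² is derived from the ADJUSTED R², the complexity-corrected fit
measure this package uses for model comparison.

Also included: compounding of per-modality subject attrition (a subject
must have complete data in every modality to enter a complete-case
multimodal analysis) and the percent reduction in required sample size
between two designs.
"""

from __future__ import annotations

import math

from scipy import optimize, stats

__all__ = [
    "cohens_f2_from_adj_r2",
    "adj_r2_from_f2",
    "regression_f_power",
    "required_sample_size",
    "cumulative_attrition",
    "sample_size_reduction",
]


def cohens_f2_from_adj_r2(adj_r2: float) -> float:
    """Cohen's effect size f² = R²/(1−R²) from an (adjusted) R²."""
    if adj_r2 >= 1.0:
        raise ValueError(f"adjusted R-squared must be < 1, got {adj_r2}")
    return adj_r2 / (1.0 - adj_r2)


def adj_r2_from_f2(f2: float) -> float:
    """Inverse map: R² = f²/(1+f²)."""
    if f2 < 0:
        raise ValueError(f"f-squared must be >= 0, got {f2}")
    return f2 / (1.0 + f2)


def regression_f_power(n: int, u: int, f2: float, alpha: float = 0.05) -> float:
    """Power of the overall F-test of a regression with u covariates.

    power = P( F′(u, n−u−1, λ=f²·n) > F_crit(1−α; u, n−u−1) ).
    """
    if u < 1:
        raise ValueError(f"u must be >= 1, got {u}")
    if n < u + 2:
        raise ValueError(f"need n >= u + 2 (n={n}, u={u})")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if f2 < 0:
        raise ValueError(f"f-squared must be >= 0, got {f2}")
    v = n - u - 1
    crit = stats.f.isf(alpha, u, v)
    if f2 == 0.0:
        return float(alpha)
    return float(stats.ncf.sf(crit, u, v, f2 * n))


def _power_real_n(n: float, u: int, f2: float, alpha: float) -> float:
    """Power at a (possibly non-integer) sample size; df enter the F
    distribution as reals, as in standard power software."""
    v = n - u - 1
    crit = stats.f.isf(alpha, u, v)
    return float(stats.ncf.sf(crit, u, v, f2 * n))


def required_sample_size(
    u: int,
    f2: float,
    target_power: float = 0.9,
    alpha: float = 0.05,
    rounding: str = "nearest",
) -> int:
    """Sample size for the overall regression F-test to reach target power.

    Solves the continuous power equation power(n) = target_power in real
    n (power is strictly increasing in n) and rounds the solution to an
    integer — to nearest by default, the convention of the standard
    power packages this module mirrors; ``rounding='ceil'`` gives the
    conservative smallest integer n whose power meets the target.
    """
    if f2 <= 0:
        raise ValueError(f"f-squared must be > 0, got {f2}")
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target_power must be in (0, 1), got {target_power}")
    if rounding not in ("nearest", "ceil"):
        raise ValueError(f"rounding must be 'nearest' or 'ceil', got {rounding!r}")
    lo = u + 2.0
    if _power_real_n(lo, u, f2, alpha) >= target_power:
        return int(lo)
    hi = lo + 1.0
    while _power_real_n(hi, u, f2, alpha) < target_power:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - pathological inputs
            raise RuntimeError("required sample size exceeds 1e8")
    n_star = optimize.brentq(
        lambda n: _power_real_n(n, u, f2, alpha) - target_power, lo, hi, xtol=1e-10
    )
    if rounding == "ceil":
        return max(int(math.ceil(n_star - 1e-9)), u + 2)
    return max(int(math.floor(n_star + 0.5)), u + 2)


def cumulative_attrition(rate_per_modality: float, n_modalities: int) -> float:
    """Fraction of subjects lost when each of m modalities independently
    drops a fraction r: 1 − (1 − r)^m."""
    if not 0.0 <= rate_per_modality < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate_per_modality}")
    if n_modalities < 1:
        raise ValueError(f"n_modalities must be >= 1, got {n_modalities}")
    return 1.0 - (1.0 - rate_per_modality) ** n_modalities


def sample_size_reduction(n_large: float, n_small: float) -> float:
    """Percent reduction 100·(n_large − n_small)/n_large."""
    if n_large <= 0:
        raise ValueError(f"n_large must be > 0, got {n_large}")
    return 100.0 * (n_large - n_small) / n_large
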