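"""Seeded generator of synthetic multimodal imaging cohorts.

Emulates the structure of a two-group neuroimaging study: a
subjects-by-features table over the full ROI × metric × region grid,
with (a) group mean shifts on a planted feature subset, (b) latent
factors — one per tissue region — that tie imaging features to the
cognitive outcomes, and (c) follow-up missingness in the patient group.

The latent-factor construction is deliberate: because the outcome loads
on region-level factors rather than on individual features, information
about the outcome is spread across many features in several metrics and
regions, so an integrative model over all modalities genuinely
outperforms any single-metric model — the qualitative regime the
analysis pipeline is designed for.

Generative model, subject i, feature j (region r(j), metric m(j)):

    h_i ~ N(0, I_q)                                 latent factors
    X_ij = mu_m + s_m * ( delta_j*[i in PWH] + a_j * h_{i,r(j)} + e_ij )

with e_ij ~ N(0, noise_sd_j²); delta_j and a_j are standardized (unit
= one within-group feature SD).  Six cognitive domain scores are linear
in h plus noise, clipped at ±clip_limit, and summed to the total score
Z; the change score dZ is linear in h plus noise for the PWH follow-up
subset.  All draws flow from one seeded generator in a fixed order
(features, then outcomes, then follow-up missingness).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .feature_model import (
    CohortOutcomes,
    FeatureDescriptor,
    FeatureTable,
    REGIONS,
    default_feature_grid,
)

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "oracle_r2", "clip_z"]

# Per-metric (location, scale) families, sized to resemble typical ROI-mean
# magnitudes of each MRI metric (diffusivity in mm^2/s, thickness in mm, ...).
METRIC_FAMILIES: dict[str, tuple[float, float]] = {
    "Vol": (0.20, 0.04),
    "CT": (2.60, 0.15),
    "FD": (2.10, 0.05),
    "FW": (0.10, 0.03),
    "FA": (0.40, 0.03),
    "MD": (0.0008, 0.0001),
    "CBF": (1.20, 0.20),
    "CVR": (1.00, 0.30),
}

#: planted group-shift / outcome-relevant feature counts per region
DEFAULT_PLANTED_BY_REGION = {"cor": 11, "sub": 23, "wm": 5}


@dataclass
class SimConfig:
    """Study-shaped simulation parameters; all defaults are the study's."""

    n_control: int = 56
    n_pwh: int = 30
    n_pwh_followup: int = 27
    grid: list[FeatureDescriptor] = field(default_factory=default_feature_grid)
    planted_by_region: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_BY_REGION)
    )
    group_shift: float = 0.8  # delta_j on planted features, within-group SD units
    factor_loading: float = 0.6  # a_j on planted features, SD units
    feature_noise_sd: float = 0.8  # e_ij SD, in feature SD units
    n_domains: int = 6
    #: per-domain loading on each region factor (domains tap all regions weakly)
    domain_loading: float = 0.35
    domain_noise_sd: float = 0.8
    #: change-score loadings per region factor and noise SD
    delta_loadings: tuple[float, ...] = (0.7, 0.9, 0.5)
    delta_noise_sd: float = 1.0
    clip_limit: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible simulation")
        if not 0 <= self.n_pwh_followup <= self.n_pwh:
            raise ValueError("need 0 <= n_pwh_followup <= n_pwh")
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        if min(self.feature_noise_sd, self.domain_noise_sd, self.delta_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")  # exactly 0 = degenerate limit
        for region, count in self.planted_by_region.items():
            avail = sum(1 for d in self.grid if d.region == region)
            if count > avail:
                raise ValueError(
                    f"cannot plant {count} features in region {region!r} "
                    f"with only {avail} available"
                )

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_pwh

    @property
    def q(self) -> int:
        """Latent-factor count: one factor per tissue region."""
        return len(REGIONS)


@dataclass
class SimTruth:
    """Generative ground truth for parameter-recovery checks."""

    feature_ids: list[str]
    delta: np.ndarray  # per-feature group shift (SD units)
    outcome_relevant: np.ndarray  # True where a_j != 0
    oracle_r2_z: float
    oracle_r2_delta_z: float


def clip_z(score: float | np.ndarray, limit: float = 3.0) -> float | np.ndarray:
    """Clamp a z-score to ±limit (outlier winsorization of domain scores)."""
    if limit <= 0:
        raise ValueError("limit must be > 0")
    return np.clip(score, -limit, limit)


def _planted_mask(config: SimConfig) -> np.ndarray:
    """Deterministic planted subset per region: evenly spaced columns.

    The grid orders each region's columns metric-major, so evenly spaced
    positions spread the planted signal across that region's metrics.
    """
    mask = np.zeros(len(config.grid), dtype=bool)
    for region, count in config.planted_by_region.items():
        idx = [j for j, d in enumerate(config.grid) if d.region == region]
        if not idx or count == 0:
            continue
        pos = sorted(set(np.linspace(0, len(idx) - 1, count).round().astype(int)))
        unused = (t for t in range(len(idx)) if t not in pos)
        while len(pos) < count:  # rounding collisions: pad with unused columns
            pos.append(next(unused))
        mask[[idx[t] for t in sorted(pos)]] = True
    return mask


def simulate_cohort(config: SimConfig) -> tuple[FeatureTable, CohortOutcomes, SimTruth]:
    """Draw one cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    grid = config.grid
    p = len(grid)
    region_index = {r: k for k, r in enumerate(REGIONS)}

    subject_ids = [f"C{i + 1:03d}" for i in range(config.n_control)] + [
        f"P{i + 1:03d}" for i in range(config.n_pwh)
    ]
    is_pwh = np.array([0] * config.n_control + [1] * config.n_pwh, dtype=float)

    planted = _planted_mask(config)
    delta = np.where(planted, config.group_shift, 0.0)
    a = np.where(planted, config.factor_loading, 0.0)
    factor_of = np.array([region_index[d.region] for d in grid])

    # --- features ------------------------------------------------------
    h = rng.standard_normal((n, config.q))
    eps = rng.standard_normal((n, p)) * config.feature_noise_sd
    std_signal = delta * is_pwh[:, None] + a * h[:, factor_of] + eps
    loc = np.array([METRIC_FAMILIES[d.metric][0] for d in grid])
    scale = np.array([METRIC_FAMILIES[d.metric][1] for d in grid])
    X = loc + scale * std_signal

    table = FeatureTable(
        pd.DataFrame(X, index=pd.Index(subject_ids, name="subject_id"),
                     columns=[d.feature_id for d in grid]),
        grid,
    )

    # --- outcomes ------------------------------------------------------
    B = np.full((config.n_domains, config.q), config.domain_loading)
    domain_noise = rng.standard_normal((n, config.n_domains)) * config.domain_noise_sd
    domains = clip_z(h @ B.T + domain_noise, config.clip_limit)
    z_baseline = domains.sum(axis=1)

    gamma = np.asarray(config.delta_loadings, dtype=float)
    if gamma.size != config.q:
        raise ValueError(f"delta_loadings must have length {config.q}")
    dz_all = h @ gamma + rng.standard_normal(n) * config.delta_noise_sd

    # --- follow-up missingness (PWH only) ------------------------------
    pwh_rows = np.flatnonzero(is_pwh == 1.0)
    followed = rng.choice(pwh_rows, size=config.n_pwh_followup, replace=False)
    followed = np.sort(followed)
    z_followup = np.full(n, np.nan)
    z_followup[followed] = z_baseline[followed] + dz_all[followed]

    outcomes = CohortOutcomes(
        pd.DataFrame(
            {
                "subject_id": subject_ids,
                "group": np.where(is_pwh == 1.0, "PWH", "control"),
                "z_baseline": z_baseline,
                "z_followup": z_followup,
            }
        )
    )

    truth = SimTruth(
        feature_ids=[d.feature_id for d in grid],
        delta=delta,
        outcome_relevant=a != 0.0,
        oracle_r2_z=oracle_r2(config, "Z"),
        oracle_r2_delta_z=oracle_r2(config, "deltaZ"),
    )
    return table, outcomes, truth


def oracle_r2(config: SimConfig, outcome: str, mc_n: int = 200_000) -> float:
    """Population R² of the best linear predictor of the outcome from the
    latent factors.

    For the change score (no clipping) this is closed form:
    R² = |γ|² / (|γ|² + σ²_noise) since Var(h) = I.  For the baseline
    total score, clipping of the domain scores makes the moments
    non-Gaussian, so Cov(Z, h) and Var(Z) are estimated by seeded Monte
    Carlo (the returned value carries O(1/sqrt(mc_n)) error).
    """
    if outcome == "deltaZ":
        gamma = np.asarray(config.delta_loadings, dtype=float)
        explained = float(gamma @ gamma)
        return explained / (explained + config.delta_noise_sd**2)
    if outcome != "Z":
        raise ValueError(f"unknown outcome {outcome!r}")
    rng = np.random.default_rng(202_406)  # fixed internal stream: an estimate
    h = rng.standard_normal((mc_n, config.q))
    B = np.full((config.n_domains, config.q), config.domain_loading)
    noise = rng.standard_normal((mc_n, config.n_domains)) * config.domain_noise_sd
    z = np.asarray(clip_z(h @ B.T + noise, config.clip_limit)).sum(axis=1)
    cov = h.T @ (z - z.mean()) / (mc_n - 1)  # Cov(h, Z); Var(h) ≈ I
    var_h = np.cov(h.T)
    explained = float(cov @ np.linalg.solve(var_h, cov))
    return explained / float(z.var(ddof=1))
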