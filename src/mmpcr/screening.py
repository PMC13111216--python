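"""Marginal feature screening by Welch's two-sample t-test.

Each imaging feature is tested for a mean difference between the patient
and control groups at baseline.  Screening is deliberately "soft": the
default threshold p < 0.2 retains weakly associated features for the
downstream integrative model, and no multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_model import CohortOutcomes, FeatureTable

__all__ = ["WelchResult", "welch_t_test", "screen_features"]

DEFAULT_THRESHOLD = 0.2


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    welch_df: float
    p_value: float


def welch_t_test(x: np.ndarray, y: np.ndarray) -> WelchResult:
    """Welch's unequal-variance t-test for a difference in means.

    t = (x̄ − ȳ) / sqrt(s²_x/n_x + s²_y/n_y), with Welch–Satterthwaite
    degrees of freedom and a two-sided p-value.  If both samples are
    constant with equal means the test is degenerate and returns
    (t=0, df=n_x+n_y−2, p=1) so that screening is total over real tables;
    constant samples with different means give p=0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError(f"each group needs >= 2 observations, got {nx} and {ny}")
    # constancy checked on raw values: var() of a bitwise-constant column can
    # pick up mean-subtraction roundoff and fabricate a huge t statistic
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        if x[0] == y[0]:
            return WelchResult(0.0, float(nx + ny - 2), 1.0)
        return WelchResult(float(np.sign(x[0] - y[0]) * np.inf), float(nx + ny - 2), 0.0)
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    diff = x.mean() - y.mean()
    se2 = vx / nx + vy / ny
    t = diff / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def screen_features(
    table: FeatureTable,
    outcomes: CohortOutcomes,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-feature Welch test of PWH vs control; select where p < threshold.

    Returns one row per feature, in the table's column order, with columns
    feature_id, region, metric, t_stat, welch_df, p_value, selected.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    groups = outcomes.group_of()
    missing = [s for s in table.subject_ids if s not in groups.index]
    if missing:
        raise ValueError(f"subjects without a group label: {missing[:5]}")
    labels = groups.loc[table.subject_ids].to_numpy()
    pwh = labels == "PWH"
    ctl = labels == "control"
    if pwh.sum() < 2 or ctl.sum() < 2:
        raise ValueError(
            f"each group needs >= 2 subjects, got PWH={int(pwh.sum())}, "
            f"control={int(ctl.sum())}"
        )
    X = table.values
    rows = []
    for j, desc in enumerate(table.descriptors):
        res = welch_t_test(X[pwh, j], X[ctl, j])
        rows.append(
            {
                "feature_id": desc.feature_id,
                "region": desc.region,
                "metric": desc.metric,
                "t_stat": res.t_stat,
                "welch_df": res.welch_df,
                "p_value": res.p_value,
                "selected": res.p_value < threshold,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    out.attrs["selected_by_region"] = (
        out.loc[out["selected"], "region"].value_counts().to_dict()
    )
    return out
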