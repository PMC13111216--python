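"""Feature identifiers, feature grids, cohort outcomes, and tabular I/O.

Imaging features are named ``ROI.METRIC.REGION`` (e.g. ``Amyg.CBF.sub``):
a region of interest, one of eight MRI-derived metrics, and the tissue
class the ROI belongs to.  Each tissue class admits only the metrics that
are physically defined there — cortical grey matter has no subcortical
volume, white matter carries only diffusion measures.

The study design this package models collects one mean value per
(ROI, metric) cell per subject, giving a subjects-by-features table with
far more features than subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METRICS",
    "REGIONS",
    "REGION_METRICS",
    "CORTICAL_ROIS",
    "SUBCORTICAL_ROIS",
    "WM_ROIS",
    "FeatureIdError",
    "FeatureDescriptor",
    "FeatureTable",
    "CohortOutcomes",
    "parse_feature_id",
    "build_feature_grid",
    "default_feature_grid",
    "compute_delta_z",
    "read_feature_table",
    "write_feature_table",
    "read_outcomes",
    "write_outcomes",
    "write_weight_table",
]

#: The eight imaging metrics, in canonical reporting order.
METRICS: tuple[str, ...] = ("Vol", "CT", "FD", "FW", "FA", "MD", "CBF", "CVR")

#: Tissue-region codes as printed in feature identifiers.
REGIONS: tuple[str, ...] = ("cor", "sub", "wm")

REGION_NAMES: Mapping[str, str] = {
    "cor": "cortical",
    "sub": "subcortical",
    "wm": "white_matter",
}

#: Metrics defined for each tissue region.
REGION_METRICS: Mapping[str, tuple[str, ...]] = {
    "cor": ("CT", "FD", "FW", "FA", "MD", "CBF", "CVR"),
    "sub": ("Vol", "FD", "FW", "FA", "MD", "CBF", "CVR"),
    "wm": ("FW", "FA", "MD"),
}

# Study ROI inventory: 11 cortical, 7 subcortical, 7 white-matter regions
# (bilateral ROIs merged), yielding 77 + 49 + 21 = 147 features.
CORTICAL_ROIS: tuple[str, ...] = (
    "FRP", "IFG_O", "STG", "POC", "PHG", "LNG", "ICX", "LOC", "TMP", "SPL", "PUC",
)
SUBCORTICAL_ROIS: tuple[str, ...] = ("CN", "PUT", "GP", "TH", "Amyg", "AccN", "Hippo")
WM_ROIS: tuple[str, ...] = ("SCC", "GCC", "BCC", "PLIC", "ALIC", "SLF", "ACR")


class FeatureIdError(ValueError):
    """A feature identifier failed validation."""


def _canon_roi(roi: str) -> str:
    """Canonical ROI spelling: hyphens become underscores ("IFG-O" == "IFG_O")."""
    return roi.replace("-", "_")


@dataclass(frozen=True)
class FeatureDescriptor:
    """One column of a feature table: ROI, metric, and tissue region."""

    roi: str
    metric: str
    region: str  # one of "cor", "sub", "wm"

    def __post_init__(self) -> None:
        if self.region not in REGION_METRICS:
            raise FeatureIdError(
                f"unknown region code {self.region!r}; expected one of {REGIONS}"
            )
        if self.metric not in METRICS:
            raise FeatureIdError(
                f"unknown metric code {self.metric!r}; expected one of {METRICS}"
            )
        if self.metric not in REGION_METRICS[self.region]:
            raise FeatureIdError(
                f"metric {self.metric!r} is not defined for region {self.region!r} "
                f"(allowed: {REGION_METRICS[self.region]})"
            )
        if not self.roi:
            raise FeatureIdError("empty ROI segment")
        object.__setattr__(self, "roi", _canon_roi(self.roi))

    @property
    def feature_id(self) -> str:
        return f"{self.roi}.{self.metric}.{self.region}"

    @property
    def region_name(self) -> str:
        return REGION_NAMES[self.region]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.feature_id


def parse_feature_id(feature_id: str) -> FeatureDescriptor:
    """Parse ``ROI.METRIC.REGION`` into a validated descriptor.

    ROI spelling is hyphen/underscore-insensitive ("IFG-O" and "IFG_O"
    name the same region); the canonical form uses underscores.

    Raises
    ------
    FeatureIdError
        If the identifier is malformed, uses an unknown metric or region
        code, or pairs a metric with a region where it is undefined.
    """
    parts = feature_id.split(".")
    if len(parts) != 3 or not all(parts):
        raise FeatureIdError(
            f"malformed feature id {feature_id!r}: expected 'ROI.METRIC.REGION'"
        )
    roi, metric, region = parts
    return FeatureDescriptor(roi=roi, metric=metric, region=region)


def build_feature_grid(
    cortical_rois: Sequence[str],
    subcortical_rois: Sequence[str],
    wm_rois: Sequence[str],
) -> list[FeatureDescriptor]:
    """Cross each region's ROI list with that region's allowed metrics.

    Order is deterministic: region (cor, sub, wm), then metric in that
    region's canonical order, then ROI in the given order.
    """
    grid: list[FeatureDescriptor] = []
    for region, rois in (("cor", cortical_rois), ("sub", subcortical_rois), ("wm", wm_rois)):
        canon = [_canon_roi(r) for r in rois]
        if len(set(canon)) != len(canon):
            dupes = sorted({r for r in canon if canon.count(r) > 1})
            raise FeatureIdError(f"duplicate ROI within region {region!r}: {dupes}")
        if not canon:
            raise FeatureIdError(f"empty ROI list for region {region!r}")
        for metric in REGION_METRICS[region]:
            for roi in canon:
                grid.append(FeatureDescriptor(roi=roi, metric=metric, region=region))
    return grid


def default_feature_grid() -> list[FeatureDescriptor]:
    """The study's 147-feature grid (77 cortical, 49 subcortical, 21 WM)."""
    return build_feature_grid(CORTICAL_ROIS, SUBCORTICAL_ROIS, WM_ROIS)


class FeatureTable:
    """Subjects-by-features matrix with parsed column descriptors.

    Analysis mode is complete-case: every cell must be a finite number.
    Wraps a :class:`pandas.DataFrame` indexed by subject id.
    """

    def __init__(self, data: pd.DataFrame, descriptors: Sequence[FeatureDescriptor] | None = None):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        if len(data) < 3:
            raise ValueError(f"need at least 3 subjects, got {len(data)}")
        values = data.to_numpy(dtype=float)  # raises on non-numeric cells
        bad = np.argwhere(~np.isfinite(values))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-finite value for subject {data.index[i]!r}, "
                f"feature {data.columns[j]!r} (complete-case analysis requires finite data)"
            )
        if descriptors is None:
            descriptors = [parse_feature_id(c) for c in data.columns]
        if len(descriptors) != data.shape[1]:
            raise ValueError("descriptor count does not match column count")
        self._df = data.astype(float)
        self._df.index = self._df.index.astype(str)
        self._df.index.name = "subject_id"
        self.descriptors: list[FeatureDescriptor] = list(descriptors)
        self._df.columns = [d.feature_id for d in self.descriptors]

    # -- basic accessors -------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy(dtype=float)

    @property
    def n_subjects(self) -> int:
        return self._df.shape[0]

    @property
    def n_features(self) -> int:
        return self._df.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    # -- subsetting ------------------------------------------------------
    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        """Column subset preserving the given order."""
        keep = list(feature_ids)
        by_id = {d.feature_id: d for d in self.descriptors}
        missing = [f for f in keep if f not in by_id]
        if missing:
            raise KeyError(f"unknown feature ids: {missing}")
        return FeatureTable(self._df[keep].copy(), [by_id[f] for f in keep])

    def select_subjects(self, subject_ids: Sequence[str]) -> "FeatureTable":
        """Row subset preserving the given order."""
        return FeatureTable(self._df.loc[list(subject_ids)].copy(), self.descriptors)

    def filter_descriptors(self, *, metric: str | None = None, region: str | None = None) -> "FeatureTable":
        keep = [
            d.feature_id
            for d in self.descriptors
            if (metric is None or d.metric == metric) and (region is None or d.region == region)
        ]
        return self.select_features(keep)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureTable({self.n_subjects} subjects x {self.n_features} features)"


GROUPS = ("control", "PWH")


@dataclass
class CohortOutcomes:
    """Group labels and cognitive outcomes per subject.

    ``z_baseline`` is the total cognitive z-score Z at the first visit;
    ``z_followup`` the same score after treatment, where measured; and
    ``delta_z`` the change (follow-up minus baseline, positive meaning
    improvement).  Change-score modelling uses only PWH rows with a
    follow-up measurement.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "group", "z_baseline")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"outcome table missing columns: {missing}")
        df = df.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids in outcomes: {dupes}")
        bad_groups = sorted(set(df["group"]) - set(GROUPS))
        if bad_groups:
            raise ValueError(f"unknown group labels {bad_groups}; expected {GROUPS}")
        if df["z_baseline"].isna().any():
            raise ValueError("z_baseline must be present for every subject")
        if "z_followup" not in df.columns:
            df["z_followup"] = np.nan
        self.table = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def group_of(self) -> pd.Series:
        return self.table.set_index("subject_id")["group"]

    def pwh_followup_ids(self) -> list[str]:
        """PWH subjects with a change score available."""
        df = compute_delta_z(self).table
        mask = (df["group"] == "PWH") & df["delta_z"].notna()
        return df.loc[mask, "subject_id"].tolist()

    def outcome_vector(self, outcome: str) -> pd.Series:
        """Outcome values indexed by subject id; 'Z' or 'deltaZ'."""
        df = compute_delta_z(self).table.set_index("subject_id")
        if outcome == "Z":
            return df["z_baseline"]
        if outcome == "deltaZ":
            mask = (df["group"] == "PWH") & df["delta_z"].notna()
            return df.loc[mask, "delta_z"]
        raise ValueError(f"unknown outcome {outcome!r}; expected 'Z' or 'deltaZ'")


def compute_delta_z(outcomes: CohortOutcomes) -> CohortOutcomes:
    """Derive ``delta_z = z_followup - z_baseline`` where follow-up exists.

    Idempotent; rows without a follow-up measurement keep ``delta_z`` absent.
    """
    df = outcomes.table.copy()
    df["delta_z"] = df["z_followup"] - df["z_baseline"]
    return CohortOutcomes(df)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}[dialect]
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_feature_table(path: str, dialect: str | None = None) -> FeatureTable:
    """Read a subjects-by-features CSV/TSV: first column subject_id, headers feature ids."""
    df = pd.read_csv(
        path, sep=_sep_for(path, dialect), dtype={0: str}, float_precision="round_trip"
    )
    if df.columns[0] != "subject_id":
        raise ValueError(
            f"first column must be 'subject_id', got {df.columns[0]!r}"
        )
    df = df.set_index("subject_id")
    na = df.isna()
    if na.any().any():
        i, j = np.argwhere(na.to_numpy())[0]
        raise ValueError(
            f"missing value for subject {df.index[i]!r}, feature {df.columns[j]!r}"
        )
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric cell in feature column {col!r}") from exc
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str, dialect: str | None = None) -> None:
    table.to_frame().to_csv(path, sep=_sep_for(path, dialect))


def read_outcomes(path: str) -> CohortOutcomes:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return CohortOutcomes(df)


def write_outcomes(outcomes: CohortOutcomes, path: str) -> None:
    outcomes.table.to_csv(path, index=False)


def write_weight_table(weights, path: str, w_min: float | None = None) -> pd.DataFrame:
    """Write a ranked weight report CSV.

    Columns mirror the standard weight-report layout:
    feature_id, adjusted_weight, unadjusted_weight, mean, sd.
    When ``w_min`` is given, rows are ranked by |adjusted weight| and only
    those with |w| >= w_min retained.
    """
    from .weight_backprop import rank_and_select  # local import avoids cycle

    report = rank_and_select(weights, w_min=w_min if w_min is not None else 0.0)
    report.to_csv(path, index=False)
    return report
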