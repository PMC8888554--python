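"""The three LC-MS feature-table filtering variants.

"cleaned" removes void-eluting features (retention time < 40 s) and
features whose pooled-QC coefficient of variation exceeds 30%.
"pc_group" additionally keeps only the feature with the greatest
cumulative study-sample signal per adduct cluster (approximating one
feature per metabolite). "ion" additionally keeps only features
explicitly annotated as the protonated ([M+H]+) or deprotonated
([M-H]-) molecular ion, depending on ESI polarity.

CV uses the sample (n-1) standard deviation — the usual metabolomics QC
convention — computed on raw intensities. Features whose QC mean is zero
have an undefined CV and are removed by the cleaned filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import MetaboFeatureTable

DEFAULT_VOID_RT_MAX = 40.0
DEFAULT_QC_CV_MAX = 0.30


@dataclass
class FilterReport:
    """Bookkeeping for one filtering step."""

    filter_name: str
    n_input: int
    surviving_ids: list[str]
    removed: dict[str, list[str]] = field(default_factory=dict)
    qc_cv: dict[str, float] | None = None
    ties: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def __post_init__(self):
        if self.n_removed + len(self.surviving_ids) != self.n_input:
            raise ValueError("removed + surviving must equal the input count")

    def to_dict(self) -> dict:
        return {
            "filter": self.filter_name,
            "n_input": self.n_input,
            "n_surviving": len(self.surviving_ids),
            "removed_counts": {k: len(v) for k, v in self.removed.items()},
            "removed": self.removed,
            "surviving": self.surviving_ids,
            "ties": self.ties,
        }


def qc_cv(table: MetaboFeatureTable) -> pd.Series:
    """Per-feature coefficient of variation over the QC injections.

    CV = sample standard deviation / mean. Features with QC mean 0 get
    NaN (undefined, treated as unreliable downstream).
    """
    if len(table.qc_columns) < 2:
        raise ValueError(
            f"QC CV needs >= 2 QC columns, table has {len(table.qc_columns)}"
        )
    qc = table.intensities[table.qc_columns]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    cv = sd / mean.where(mean > 0, np.nan)
    cv.name = "qc_cv"
    return cv


def filter_cleaned(
    table: MetaboFeatureTable,
    void_rt_max: float = DEFAULT_VOID_RT_MAX,
    qc_cv_max: float = DEFAULT_QC_CV_MAX,
) -> tuple[MetaboFeatureTable, FilterReport]:
    """Remove void-eluting (RT < ``void_rt_max``) and QC-unstable features.

    A feature survives iff its retention time is >= ``void_rt_max`` (the
    rule is "eluting < 40 s", so exactly 40.0 s is retained) and its QC
    CV is defined and <= ``qc_cv_max``.
    """
    cv = qc_cv(table)
    rt = table.features["retention_time"]
    void = rt < void_rt_max
    bad_cv = ~void & (cv.isna() | (cv > qc_cv_max))
    keep = ~void & ~bad_cv
    report = FilterReport(
        filter_name="cleaned",
        n_input=len(table.feature_ids),
        surviving_ids=list(table.features.index[keep]),
        removed={
            "void": list(table.features.index[void]),
            "qc_cv": list(table.features.index[bad_cv]),
        },
        qc_cv={fid: (None if np.isnan(v) else float(v)) for fid, v in cv.items()},
    )
    return table.subset_features(report.surviving_ids), report


def filter_pc_group(
    cleaned: MetaboFeatureTable,
) -> tuple[MetaboFeatureTable, FilterReport]:
    """Keep only the maximal-cumulative-signal feature per pc_group.

    Cumulative signal is the sum of intensities over study samples (QC
    injections are pooled material, not observations). Ties break to the
    lexicographically smallest feature id and are logged in the report.
    """
    if "pc_group" not in cleaned.features.columns:
        raise ValueError("pc_group column required")
    study = cleaned.intensities[cleaned.study_columns]
    sums = study.sum(axis=1)
    survivors: list[str] = []
    ties: list[str] = []
    for _, members in cleaned.features.groupby("pc_group").groups.items():
        member_sums = sums.loc[members]
        top = member_sums[member_sums == member_sums.max()]
        winner = top.index.min()
        if len(top) > 1:
            ties.append(winner)
        survivors.append(winner)
    survivors = [fid for fid in cleaned.feature_ids if fid in set(survivors)]
    removed = [fid for fid in cleaned.feature_ids if fid not in set(survivors)]
    report = FilterReport(
        filter_name="pc_group",
        n_input=len(cleaned.feature_ids),
        surviving_ids=survivors,
        removed={"non_representative": removed},
        ties=ties,
    )
    return cleaned.subset_features(survivors), report


_UNICODE_MINUS = ("−", "‐", "‑", "–", "—")


def _normalize_annotation(ann: str) -> str:
    """Strip internal whitespace and unify Unicode minus/hyphen variants."""
    s = str(ann)
    for ch in _UNICODE_MINUS:
        s = s.replace(ch, "-")
    return re.sub(r"\s+", "", s)


def filter_ion(cleaned: MetaboFeatureTable) -> tuple[MetaboFeatureTable, FilterReport]:
    """Keep only explicit molecular-ion annotations for the ESI polarity.

    Positive mode retains "[M+H]+", negative mode "[M-H]-", after
    normalising internal whitespace and Unicode minus signs.
    """
    if cleaned.mode is None:
        raise ValueError("acquisition mode required for the ion filter")
    _, polarity = cleaned.mode
    target = "[M+H]+" if polarity == "positive" else "[M-H]-"
    ann = cleaned.features["annotation"].map(_normalize_annotation)
    keep = ann == target
    report = FilterReport(
        filter_name="ion",
        n_input=len(cleaned.feature_ids),
        surviving_ids=list(cleaned.features.index[keep]),
        removed={"non_ion": list(cleaned.features.index[~keep])},
    )
    return cleaned.subset_features(report.surviving_ids), report
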