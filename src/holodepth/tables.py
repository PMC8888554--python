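"""Core in-memory containers for the holobiont data sets.

An :class:`AsvTable` holds a samples x ASVs count (or relative-abundance)
matrix, a :class:`MetaboFeatureTable` holds an LC-MS feature x sample
intensity matrix with per-feature chromatographic metadata, and a
:class:`SequenceSet` maps ASV ids to fixed-length nucleotide sequences.
Sample metadata travels as a plain :class:`pandas.DataFrame` with a fixed
column contract (see :data:`METADATA_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Required columns of a sample-metadata frame.
METADATA_COLUMNS = (
    "sample_id",
    "species",
    "depth",
    "latitude",
    "longitude",
    "temperature",
    "salinity",
    "year",
    "water_mass",
)

#: Depth (m) separating the shallow from the deep water mass.
WATER_MASS_SPLIT_M = 1000.0

VALID_CHROMATOGRAPHY = ("HILIC", "RP")
VALID_POLARITY = ("positive", "negative")


def water_mass_label(depth_m) -> np.ndarray:
    """Classify depths into "shallow" (<= split) or "deep" (> split)."""
    depth_m = np.asarray(depth_m, dtype=float)
    return np.where(depth_m <= WATER_MASS_SPLIT_M, "shallow", "deep")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    if (meta["depth"] <= 0).any():
        raise ValueError("depths must be positive (metres)")
    expected = water_mass_label(meta["depth"].to_numpy())
    if not (meta["water_mass"].to_numpy() == expected).all():
        raise ValueError("water_mass labels inconsistent with the 1000 m rule")
    return meta


@dataclass
class AsvTable:
    """Samples x ASVs abundance matrix.

    ``data`` rows are samples, columns ASVs. ``kind`` is "counts"
    (non-negative integers) or "relabund" (rows sum to 1).
    """

    data: pd.DataFrame
    kind: str = "counts"
    taxonomy: pd.Series | None = None

    def __post_init__(self):
        if self.data.index.duplicated().any() or self.data.columns.duplicated().any():
            raise ValueError("sample and ASV ids must be unique")
        values = self.data.to_numpy()
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"ASV {self.data.columns[j]!r}"
            )
        if self.kind == "relabund":
            sums = values.sum(axis=1)
            nonempty = sums > 0
            if not np.allclose(sums[nonempty], 1.0, atol=1e-9):
                raise ValueError("relative-abundance rows must sum to 1 (1e-9)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    def relative_abundance(self) -> "AsvTable":
        """Total-sum scaled copy; all-zero samples stay all-zero."""
        if self.kind == "relabund":
            return self
        sums = self.data.sum(axis=1)
        rel = self.data.div(sums.where(sums > 0, 1.0), axis=0)
        return AsvTable(rel, kind="relabund", taxonomy=self.taxonomy)

    def subset_samples(self, sample_ids) -> "AsvTable":
        return replace(self, data=self.data.loc[list(sample_ids)])


@dataclass
class MetaboFeatureTable:
    """LC-MS feature table: intensities plus per-feature metadata.

    ``intensities`` is features x samples (study samples and QC injections
    side by side); ``features`` carries ``retention_time`` (s), ``mz``,
    ``annotation`` and ``pc_group`` indexed by feature id; ``qc_columns``
    flags which intensity columns are pooled-QC injections. ``mode`` is
    (chromatography, polarity).
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    qc_columns: list[str] = field(default_factory=list)
    mode: tuple[str, str] | None = None

    REQUIRED_FEATURE_COLUMNS = ("retention_time", "mz", "annotation", "pc_group")

    def __post_init__(self):
        if self.intensities.index.duplicated().any():
            raise ValueError("feature ids must be unique")
        missing = [
            c for c in self.REQUIRED_FEATURE_COLUMNS if c not in self.features.columns
        ]
        if missing:
            raise ValueError(f"feature metadata missing columns: {missing}")
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("feature metadata and intensity matrix ids differ")
        if (self.features["retention_time"] < 0).any():
            raise ValueError("retention_time must be >= 0 seconds")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        unknown_qc = set(self.qc_columns) - set(self.intensities.columns)
        if unknown_qc:
            raise ValueError(f"QC columns absent from the table: {sorted(unknown_qc)}")
        if self.mode is not None:
            chrom, pol = self.mode
            if chrom not in VALID_CHROMATOGRAPHY or pol not in VALID_POLARITY:
                raise ValueError(f"unknown acquisition mode {self.mode}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def study_columns(self) -> list[str]:
        qc = set(self.qc_columns)
        return [c for c in self.intensities.columns if c not in qc]

    def subset_features(self, feature_ids) -> "MetaboFeatureTable":
        ids = list(feature_ids)
        return MetaboFeatureTable(
            self.intensities.loc[ids],
            self.features.loc[ids],
            qc_columns=list(self.qc_columns),
            mode=self.mode,
        )


@dataclass
class SequenceSet:
    """Fixed-length nucleotide sequences keyed by ASV id."""

    sequences: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences must share one length, found {sorted(lengths)}")
        alphabet = set("ACGT")
        for sid, seq in self.sequences.items():
            extra = set(seq) - alphabet
            if extra:
                raise ValueError(f"sequence {sid!r} has non-ACGT symbols {sorted(extra)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]
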