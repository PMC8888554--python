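"""Readers and writers for every on-disk artifact.

Community tables are TSV (QIIME-style, orientation auto-detected from
the header sentinel), metabolomics feature tables CSV (XCMS-style, QC
injections identified by a ``QC`` column-name prefix), sequences FASTA,
networks TSV edge lists plus GraphML, and results/truth JSON. Every
writer round-trips through its paired reader.
"""

from __future__ import annotations

import json
import os

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import SyntheticTruth
from .tables import AsvTable, MetaboFeatureTable, SequenceSet, validate_metadata


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def _require_nonempty(path) -> None:
    if not os.path.exists(path):
        raise FormatError(f"{path}: file does not exist")
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path}: file is empty")


# ------------------------------------------------------------- metadata TSV

def write_metadata(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    _require_nonempty(path)
    meta = pd.read_csv(path, sep="\t")
    return validate_metadata(meta)


# ------------------------------------------------------------ ASV table TSV

SAMPLE_SENTINEL = "sample_id"
ASV_SENTINEL = "asv_id"


def write_asv_table(table: AsvTable, path) -> None:
    df = table.data.copy()
    df.index.name = SAMPLE_SENTINEL
    df.to_csv(path, sep="\t")


def read_asv_table(path) -> AsvTable:
    """Read a count TSV; orientation detected from the corner header cell."""
    _require_nonempty(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)):
        raise FormatError(f"{path}: duplicate sample or ASV ids in the header")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # ragged rows etc.
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    if df.empty:
        raise FormatError(f"{path}: table has no data rows")
    sentinel = (df.index.name or "").strip().lower()
    if sentinel == ASV_SENTINEL:
        df = df.T
    elif sentinel != SAMPLE_SENTINEL:
        raise FormatError(
            f"{path}: corner header must be '{SAMPLE_SENTINEL}' or "
            f"'{ASV_SENTINEL}', found {df.index.name!r}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric abundance values")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample or ASV ids")
    df.index.name = None
    df.columns.name = None
    kind = "counts" if np.allclose(values, np.round(values)) else "relabund"
    return AsvTable(df, kind=kind)


# ------------------------------------------------------------------- FASTA

def write_sequences(seqs: SequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in seqs.sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_sequences(path) -> SequenceSet:
    _require_nonempty(path)
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return SequenceSet({r.id: str(r.seq).upper() for r in records})


# ------------------------------------------------------- feature table CSV

FEATURE_META_COLUMNS = ("retention_time", "mz", "annotation", "pc_group")
QC_PREFIX = "QC"


def write_feature_table(table: MetaboFeatureTable, path) -> None:
    df = table.features.join(table.intensities)
    df.index.name = "feature_id"
    df.to_csv(path)


def read_feature_table(path, mode: tuple[str, str] | None = None) -> MetaboFeatureTable:
    """Read a feature CSV; QC injections are columns named ``QC*``."""
    _require_nonempty(path)
    try:
        df = pd.read_csv(path, index_col=0, keep_default_na=False, na_values=[])
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in FEATURE_META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: required column(s) missing: {missing}")
    df.index.name = None
    features = df[list(FEATURE_META_COLUMNS)].copy()
    features["retention_time"] = features["retention_time"].astype(float)
    features["mz"] = features["mz"].astype(float)
    features["pc_group"] = features["pc_group"].astype(int)
    sample_cols = [c for c in df.columns if c not in FEATURE_META_COLUMNS]
    intensities = df[sample_cols].astype(float)
    qc_cols = [c for c in sample_cols if c.startswith(QC_PREFIX)]
    return MetaboFeatureTable(intensities, features, qc_columns=qc_cols, mode=mode)


# ------------------------------------------------------------ truth / JSON

def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "responsive": truth.responsive,
        "sister_pairs": [list(t) for t in truth.sister_pairs],
        "planted_associations": [list(t) for t in truth.planted_associations],
        "qc_cv_targets": truth.qc_cv_targets,
        "void_ids": truth.void_ids,
        "high_cv_ids": truth.high_cv_ids,
        "pc_representatives": {str(k): v for k, v in truth.pc_representatives.items()},
    }
    write_json(payload, path)


def read_truth(path) -> SyntheticTruth:
    _require_nonempty(path)
    with open(path) as fh:
        raw = json.load(fh)
    return SyntheticTruth(
        responsive=dict(raw["responsive"]),
        sister_pairs=[tuple(t) for t in raw["sister_pairs"]],
        planted_associations=[tuple(t) for t in raw["planted_associations"]],
        qc_cv_targets=dict(raw["qc_cv_targets"]),
        void_ids=list(raw["void_ids"]),
        high_cv_ids=list(raw["high_cv_ids"]),
        pc_representatives={int(k): v for k, v in raw["pc_representatives"].items()},
    )


def write_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ----------------------------------------------------- matrices & networks

def write_square_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def read_square_tsv(path) -> pd.DataFrame:
    _require_nonempty(path)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_network(net, edge_path, graphml_path) -> None:
    net.edge_frame().to_csv(edge_path, sep="\t", index=False)
    g = nx.Graph()
    for a, b, attrs in sorted(net.graph.edges(data=True)):
        g.add_edge(a, b, votes=int(attrs["votes"]),
                   **{f"p_{m}": float(v) for m, v in attrs["p"].items()})
    nx.write_graphml(g, graphml_path)


def read_network_edges(path) -> pd.DataFrame:
    _require_nonempty(path)
    return pd.read_csv(path, sep="\t")
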