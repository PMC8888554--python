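"""Sister-group ASV (ecotype) detection.

Sister pairs are highly similar sequences (ungapped positional identity
>= 97% by default) whose abundances respond to depth in opposite
directions — candidate ecotypes of the two water masses. Detection
supports two bases (the depth-correlation trend classes or the
water-mass t-test with trend direction) and two stringencies (raw p or
FDR-adjusted p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import SequenceSet

DEFAULT_MIN_IDENTITY = 0.97

_BASES = ("correlation", "ttest")
_STRINGENCIES = ("raw_p", "fdr_p")


def pairwise_identity(seqs: SequenceSet) -> pd.DataFrame:
    """Symmetric matrix of ungapped positional identities.

    identity(i, j) = matching positions / length. Sequences must share
    one length (fixed-length ASVs); no alignment is attempted.
    """
    ids = seqs.ids
    if not ids:
        raise ValueError("empty sequence set")
    arr = np.frombuffer(
        "".join(seqs.sequences[i] for i in ids).encode(), dtype="S1"
    ).reshape(len(ids), seqs.length)
    matches = (arr[:, None, :] == arr[None, :, :]).sum(axis=2)
    identity = matches / seqs.length
    return pd.DataFrame(identity, index=ids, columns=ids)


def alignment_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity for variable-length inputs (optional path)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(a, b))
    return matches / len(a)


@dataclass(frozen=True)
class SisterPair:
    asv_a: str
    asv_b: str
    identity: float
    class_a: str
    class_b: str
    basis: str
    stringency: str


def _directions(
    trend_results: pd.DataFrame,
    ttest_results: pd.DataFrame | None,
    basis: str,
    stringency: str,
    alpha: float,
) -> pd.DataFrame:
    """Per-ASV signed significance under the chosen basis/stringency.

    Returns a frame with 'direction' (+1/-1/0 = not significant) and a
    human-readable 'label'.
    """
    p_col = "p" if stringency == "raw_p" else "p_fdr"
    if basis == "correlation":
        sig = trend_results[p_col] <= alpha
        sign = np.sign(trend_results["r"].fillna(0.0))
        label = trend_results["trend_class"]
    else:
        if ttest_results is None:
            raise ValueError("basis='ttest' needs water-mass t-test results")
        sig = ttest_results[p_col] <= alpha
        # Direction with depth: deeper mean larger => increasing.
        sign = np.sign(
            ttest_results["mean_deep"] - ttest_results["mean_shallow"]
        )
        label = np.where(sign > 0, "deep-enriched", "shallow-enriched")
        label = pd.Series(label, index=ttest_results.index)
    direction = np.where(sig & (sign != 0), sign, 0).astype(int)
    return pd.DataFrame({"direction": direction, "label": label}, index=label.index)


def find_sister_pairs(
    identity: pd.DataFrame,
    trend_results: pd.DataFrame,
    ttest_results: pd.DataFrame | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    basis: str = "correlation",
    stringency: str = "raw_p",
    alpha: float = 0.05,
    require_both_significant: bool = True,
) -> list[SisterPair]:
    """All unordered ASV pairs with identity >= threshold and opposing
    significant depth responses.

    By default both members must be individually significant with
    opposite signs; ``require_both_significant=False`` relaxes this to
    one significant member plus an opposite-signed (possibly
    non-significant) trend in the other.
    """
    if basis not in _BASES:
        raise ValueError(f"basis must be one of {_BASES}")
    if stringency not in _STRINGENCIES:
        raise ValueError(f"stringency must be one of {_STRINGENCIES}")
    ids = list(identity.index)
    missing = set(ids) - set(trend_results.index)
    if missing:
        raise ValueError(f"trend results missing ASVs: {sorted(missing)[:5]}")

    dirs = _directions(trend_results, ttest_results, basis, stringency, alpha)
    # Sign of the (possibly non-significant) trend, for the relaxed rule.
    if basis == "correlation":
        soft_sign = np.sign(trend_results["r"].fillna(0.0)).reindex(ids)
    else:
        soft_sign = np.sign(
            (ttest_results["mean_deep"] - ttest_results["mean_shallow"])
        ).reindex(ids)

    pairs: list[SisterPair] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if identity.loc[a, b] < min_identity:
                continue
            da, db = int(dirs.loc[a, "direction"]), int(dirs.loc[b, "direction"])
            if require_both_significant:
                opposing = da * db == -1
            else:
                opposing = (
                    da * db == -1
                    or (da != 0 and soft_sign[b] == -da)
                    or (db != 0 and soft_sign[a] == -db)
                )
            if not opposing:
                continue
            a_, b_ = sorted([a, b])
            pairs.append(
                SisterPair(
                    asv_a=a_,
                    asv_b=b_,
                    identity=float(identity.loc[a, b]),
                    class_a=str(dirs.loc[a_, "label"]),
                    class_b=str(dirs.loc[b_, "label"]),
                    basis=basis,
                    stringency=stringency,
                )
            )
    pairs.sort(key=lambda p: (p.asv_a, p.asv_b))
    return pairs


def sister_pairs_frame(pairs: list[SisterPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "asv_a": p.asv_a,
                "asv_b": p.asv_b,
                "identity": p.identity,
                "class_a": p.class_a,
                "class_b": p.class_b,
                "basis": p.basis,
                "stringency": p.stringency,
            }
            for p in pairs
        ],
        columns=[
            "asv_a",
            "asv_b",
            "identity",
            "class_a",
            "class_b",
            "basis",
            "stringency",
        ],
    )
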