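"""Linking the microbiota to the metabolome.

A Mantel test relates the community (Bray-Curtis) and metabolome
(Euclidean on log-transformed, feature-autoscaled intensities)
dissimilarity structures; a Procrustes rotation test compares their
ordinations; and per-compound Spearman rankings nominate ASVs whose
abundance tracks the signal of specific compound groups (the top ten
positive correlations per compound, compared across groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._utils import add_one_p, exhaustive_permutations, spawn_rng
from .community import DistanceMatrix

DEFAULT_TOP_K = 10


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int


def _offdiag_corr(a: np.ndarray, b: np.ndarray) -> float:
    iu = np.triu_indices(a.shape[0], 1)
    x, y = a[iu], b[iu]
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc**2).sum() * (yc**2).sum()))


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int | str = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel statistic (Pearson r of off-diagonals) with permutation p.

    Matrices are aligned by sample id; p comes from permuting the rows
    and columns of the second matrix (seeded, add-one estimator, upper
    tail). ``n_perm="exhaustive"`` enumerates all n! relabelings.
    """
    ids1, ids2 = set(d1.sample_ids), set(d2.sample_ids)
    if ids1 != ids2:
        raise ValueError(
            f"sample sets differ: only-in-first={sorted(ids1 - ids2)}, "
            f"only-in-second={sorted(ids2 - ids1)}"
        )
    a = d1.values()
    b = d2.data.loc[d1.sample_ids, d1.sample_ids].to_numpy(dtype=float)
    r_obs = _offdiag_corr(a, b)
    n = a.shape[0]
    if n_perm == "exhaustive":
        perms = list(exhaustive_permutations(n))
        hits = sum(
            _offdiag_corr(a, b[np.ix_(p, p)]) >= r_obs - 1e-12 for p in perms
        )
        return MantelResult(r=r_obs, p=hits / len(perms), n_permutations=len(perms))
    rng = spawn_rng(seed, "mantel")
    hits = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        if _offdiag_corr(a, b[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r=r_obs, p=add_one_p(hits, int(n_perm)),
                        n_permutations=int(n_perm))


@dataclass
class ProcrustesResult:
    m2: float
    p: float
    n_permutations: int


def _procrustes_m2(x: np.ndarray, y: np.ndarray, allow_reflection: bool) -> float:
    """Normalized residual m^2 after optimal translation/rotation/scaling."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xc /= np.linalg.norm(xc)
    yc /= np.linalg.norm(yc)
    u, s, vt = np.linalg.svd(xc.T @ yc)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        s = s.copy()
        s[-1] = -s[-1]
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_test(
    scores1: pd.DataFrame,
    scores2: pd.DataFrame,
    n_perm: int | str = 999,
    seed: int = 0,
    allow_reflection: bool = True,
) -> ProcrustesResult:
    """Procrustes m^2 with a permutation test (PROTEST-style).

    m^2 in [0, 1] is the residual after superimposing the second
    configuration on the first; p permutes the sample labels of the
    second configuration (lower tail: smaller m^2 is a better match).
    """
    if scores1.shape[1] != scores2.shape[1]:
        raise ValueError(
            f"dimension mismatch: {scores1.shape[1]} vs {scores2.shape[1]}"
        )
    y = scores2.loc[scores1.index].to_numpy(dtype=float)
    x = scores1.to_numpy(dtype=float)
    m2_obs = _procrustes_m2(x, y, allow_reflection)
    n = x.shape[0]
    if n_perm == "exhaustive":
        perms = list(exhaustive_permutations(n))
        hits = sum(
            _procrustes_m2(x, y[list(p)], allow_reflection) <= m2_obs + 1e-12
            for p in perms
        )
        return ProcrustesResult(m2=m2_obs, p=hits / len(perms),
                                n_permutations=len(perms))
    rng = spawn_rng(seed, "procrustes")
    hits = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        if _procrustes_m2(x, y[perm], allow_reflection) <= m2_obs + 1e-12:
            hits += 1
    return ProcrustesResult(m2=m2_obs, p=add_one_p(hits, int(n_perm)),
                            n_permutations=int(n_perm))


def metabolome_distance(intensities: pd.DataFrame, log: bool = True,
                        autoscale: bool = True) -> DistanceMatrix:
    """Euclidean dissimilarity between samples of a feature table.

    Columns are samples. Intensities are log-transformed (log1p) and
    feature-autoscaled (zero mean, unit variance) by default.
    """
    from scipy.spatial.distance import pdist, squareform

    x = intensities.to_numpy(dtype=float).T  # samples x features
    if log:
        x = np.log1p(x)
    if autoscale:
        sd = x.std(axis=0, ddof=1)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    d = squareform(pdist(x, metric="euclidean"))
    ids = list(intensities.columns)
    return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids),
                          metric="euclidean")


@dataclass
class CompoundLinkTable:
    """Ranked positive ASV-compound correlations.

    per_compound: compound id -> frame (asv, rho, p) ranked by
    descending rho over positive correlations only (<= top_k rows).
    group_top_sets: compound group -> ASV membership counts across the
    group's compound top lists. intersection: ASVs in the top lists of
    every group.
    """

    per_compound: dict[str, pd.DataFrame] = field(default_factory=dict)
    group_top_sets: dict[str, pd.Series] = field(default_factory=dict)
    intersection: set[str] = field(default_factory=set)
    excluded_compounds: list[str] = field(default_factory=list)


def link_asvs_to_compounds(
    asv_table,
    compound_signals: pd.DataFrame,
    compound_groups: dict[str, list[str]],
    top_k: int = DEFAULT_TOP_K,
) -> CompoundLinkTable:
    """Spearman-rank ASVs against compound signals and compare top sets.

    ``compound_signals`` is compounds x samples; ``compound_groups``
    partitions its compounds. Constant-signal compounds are flagged and
    excluded. Output does not depend on input row/column order.
    """
    rel = asv_table.relative_abundance().data  # samples x ASVs
    shared = [s for s in rel.index if s in compound_signals.columns]
    if not shared:
        raise ValueError("no shared samples between ASVs and compounds")
    rel = rel.loc[shared]
    signals = compound_signals[shared]

    out = CompoundLinkTable()
    for compound in sorted(signals.index):
        sig = signals.loc[compound].to_numpy(dtype=float)
        if np.ptp(sig) == 0:
            out.excluded_compounds.append(compound)
            continue
        rho, p = spearmanr(rel.to_numpy(dtype=float), sig)
        # spearmanr on (n, k) + vector returns (k+1, k+1); last row vs vars
        rho = np.atleast_2d(rho)[-1, :-1]
        p = np.atleast_2d(p)[-1, :-1]
        frame = pd.DataFrame({"asv": rel.columns, "rho": rho, "p": p})
        frame = frame[frame["rho"] > 0]
        frame = frame.sort_values(["rho", "asv"], ascending=[False, True])
        out.per_compound[compound] = frame.head(top_k).reset_index(drop=True)

    for group in sorted(compound_groups):
        counts: dict[str, int] = {}
        for compound in compound_groups[group]:
            if compound not in out.per_compound:
                continue
            for asv in out.per_compound[compound]["asv"]:
                counts[asv] = counts.get(asv, 0) + 1
        out.group_top_sets[group] = pd.Series(counts, dtype=int).sort_index()

    sets = [set(s.index) for s in out.group_top_sets.values() if len(s)]
    out.intersection = set.intersection(*sets) if sets else set()
    return out
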