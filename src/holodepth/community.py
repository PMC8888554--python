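"""Community-level statistics.

Alpha diversity, Bray-Curtis dissimilarity, one-factor PERMANOVA with
seeded (or exhaustive) permutations, metric ordination (principal
coordinates) with sign canonicalisation, environmental vector fitting,
variance-inflation screening, transformation selection by rank
correlation against a gradient, and average-linkage (UPGMA) clustering.

Ordination uses classical metric scaling rather than the iterative
stress-minimising NMDS common in ecology: the score space is
deterministic and exactly checkable against the eigen-decomposition,
which matters for seeded reproducibility; an NMDS refinement is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from ._utils import add_one_p, check_square_symmetric, exhaustive_permutations, spawn_rng


# ---------------------------------------------------------------- diversity

def alpha_diversity(asv_table) -> pd.DataFrame:
    """Per-sample richness, Shannon entropy (nats) and inverse Simpson.

    Empty samples get NaN diversity (flagged, not an error).
    """
    counts = asv_table.data.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    richness = (counts > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / totals[:, None]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        shannon = -plogp.sum(axis=1)
        inv_simpson = 1.0 / (p**2).sum(axis=1)
    shannon[totals == 0] = np.nan
    inv_simpson[totals == 0] = np.nan
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon, "inv_simpson": inv_simpson},
        index=asv_table.data.index,
    )


# ------------------------------------------------------------- dissimilarity

@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    data: pd.DataFrame
    metric: str = "bray-curtis"

    def __post_init__(self):
        check_square_symmetric(self.data.to_numpy(), "distance matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def condensed(self) -> np.ndarray:
        return squareform(self.values(), checks=False)


def bray_curtis(asv_table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y).

    A pair of all-zero samples has an undefined distance; it is flagged
    by raising, since downstream permutation statistics cannot use it.
    """
    x = asv_table.data.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("two all-zero samples: Bray-Curtis undefined for that pair")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(
        pd.DataFrame(d, index=asv_table.data.index, columns=asv_table.data.index),
        metric="bray-curtis",
    )


# ----------------------------------------------------------------- PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances (Anderson's partition)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    a = groups.size
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


def permanova(
    dist: DistanceMatrix,
    grouping,
    n_perm: int | str = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA with seeded label permutations.

    ``n_perm="exhaustive"`` enumerates all label permutations (tiny n
    only); otherwise p uses the add-one estimator (1+B)/(1+N).
    """
    d = dist.values()
    labels = np.asarray(grouping)
    if labels.size != d.shape[0]:
        raise ValueError("grouping length must match the distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).all():
        raise ValueError("grouping has only singleton groups")
    d2 = d**2
    f_obs, r2 = _pseudo_f(d2, labels)
    if n_perm == "exhaustive":
        perms = list(exhaustive_permutations(labels.size))
        f_perm = np.array([_pseudo_f(d2, labels[list(p)])[0] for p in perms])
        p = float((f_perm >= f_obs - 1e-12).sum() / len(perms))
        n_used = len(perms)
    else:
        rng = spawn_rng(seed, "permanova")
        hits = 0
        for _ in range(int(n_perm)):
            perm = rng.permutation(labels.size)
            if _pseudo_f(d2, labels[perm])[0] >= f_obs - 1e-12:
                hits += 1
        p = add_one_p(hits, int(n_perm))
        n_used = int(n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2), p=p, n_permutations=n_used)


# ---------------------------------------------------------------- ordination

def ordinate(dist: DistanceMatrix, k: int = 2) -> pd.DataFrame:
    """Principal-coordinate scores (classical metric scaling).

    Axis signs are canonicalised (first nonzero loading positive) so
    repeated runs yield identical scores.
    """
    d = dist.values()
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-9).sum())
    if k > n_pos:
        raise ValueError(
            f"requested {k} axes but only {n_pos} positive eigenvalues; "
            f"spectrum head: {np.round(evals[: k + 2], 6).tolist()}"
        )
    scores = evecs[:, :k] * np.sqrt(evals[:k])
    for a in range(k):
        col = scores[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            scores[:, a] = -col
    return pd.DataFrame(
        scores, index=dist.sample_ids, columns=[f"PCo{a + 1}" for a in range(k)]
    )


def nmds(dist: DistanceMatrix, k: int = 2, seed: int = 0, max_iter: int = 300):
    """Optional stress-minimising NMDS refinement of the metric scores."""
    from sklearn.manifold import MDS  # lazy; only for the optional path

    m = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        random_state=int(seed) % (2**32),
        max_iter=max_iter,
        normalized_stress="auto",
        n_init=4,
    )
    scores = m.fit_transform(dist.values())
    return pd.DataFrame(
        scores, index=dist.sample_ids, columns=[f"NMDS{a + 1}" for a in range(k)]
    )


# -------------------------------------------------------------------- envfit

@dataclass
class EnvFitResult:
    variable: str
    direction: tuple[float, ...]
    r2: float
    p: float


def envfit(
    scores: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> list[EnvFitResult]:
    """Fit environmental vectors onto a 2-D ordination.

    Per variable: least-squares direction in score space, r^2 = fraction
    of the variable's variance explained by the scores, permutation p by
    shuffling the variable across samples (seeded, add-one).
    Constant variables are flagged with NaN r^2 and p = 1.
    """
    if scores.shape[1] != 2:
        raise ValueError("envfit expects k=2 ordination scores")
    if not scores.index.equals(env.index):
        env = env.loc[scores.index]
    s = scores.to_numpy(dtype=float)
    sc = s - s.mean(axis=0)
    pinv = np.linalg.pinv(sc)
    hat = sc @ pinv  # projection onto the (centred) score space
    rng = spawn_rng(seed, "envfit")
    results = []
    for name in env.columns:
        v = env[name].to_numpy(dtype=float)
        vc = v - v.mean()
        if (vc**2).sum() == 0:
            results.append(EnvFitResult(name, (np.nan, np.nan), np.nan, 1.0))
            continue
        beta = pinv @ vc
        r2_obs = float(((hat @ vc) ** 2).sum() / (vc**2).sum())
        norm = np.linalg.norm(beta)
        direction = tuple((beta / norm) if norm > 0 else beta)
        hits = 0
        for _ in range(n_perm):
            vp = rng.permutation(vc)
            r2p = ((hat @ vp) ** 2).sum() / (vp**2).sum()
            if r2p >= r2_obs - 1e-12:
                hits += 1
        results.append(
            EnvFitResult(name, direction, r2_obs, add_one_p(hits, n_perm))
        )
    return results


# ------------------------------------------------------------------ VIF

def vif_screen(env: pd.DataFrame, threshold: float = 10.0) -> tuple[list[str], dict]:
    """Iteratively drop the largest-VIF variable until all VIF < threshold.

    VIF_j = 1/(1 - R^2_j) from regressing variable j on the others
    (variables standardised first). Perfectly collinear variables have
    infinite VIF and are removed first.
    """
    if env.shape[1] < 2:
        raise ValueError("need >= 2 variables")
    if env.shape[0] <= env.shape[1]:
        raise ValueError("need more samples than variables")
    kept = list(env.columns)
    history: dict[str, float] = {}

    def _vifs(cols: list[str]) -> pd.Series:
        x = env[cols].to_numpy(dtype=float)
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
        out = {}
        for j, name in enumerate(cols):
            others = np.delete(x, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
            resid = x[:, j] - others @ beta
            r2 = 1.0 - (resid**2).sum() / (x[:, j] ** 2).sum()
            out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    while len(kept) >= 2:
        vifs = _vifs(kept)
        worst = vifs.idxmax()
        if vifs[worst] < threshold:
            break
        history[worst] = float(vifs[worst])
        kept.remove(worst)
    final = _vifs(kept) if len(kept) >= 2 else pd.Series({kept[0]: 1.0})
    return kept, {**history, **{k: float(v) for k, v in final.items()}}


# ------------------------------------------------- transformation selection

TRANSFORMATIONS = {
    "identity": lambda x: x,
    "relabund": lambda x: x / np.maximum(x.sum(axis=1, keepdims=True), 1e-300),
    "sqrt": np.sqrt,
    "log1p": np.log1p,
    "presence": lambda x: (x > 0).astype(float),
}


def select_transformation(
    asv_table,
    gradient,
    candidates: list[str] | None = None,
) -> tuple[str, dict[str, float]]:
    """Pick the transformation whose Bray-Curtis dissimilarities best rank-
    correlate with pairwise gradient separation."""
    from scipy.stats import spearmanr

    gradient = np.asarray(gradient, dtype=float)
    if np.ptp(gradient) == 0:
        raise ValueError("gradient is constant")
    candidates = candidates or list(TRANSFORMATIONS)
    if not candidates:
        raise ValueError("no candidate transformations")
    x = asv_table.data.to_numpy(dtype=float)
    gdist = pdist(gradient[:, None], metric="cityblock")
    scores: dict[str, float] = {}
    for name in candidates:
        t = TRANSFORMATIONS[name](x)
        d = pdist(t, metric="braycurtis")
        scores[name] = float(spearmanr(d, gdist).statistic)
    best = max(scores, key=lambda k: (scores[k], -candidates.index(k)))
    return best, scores


# --------------------------------------------------------------- clustering

def upgma_cluster(dist: DistanceMatrix, n_clusters: int = 2):
    """Average-linkage (UPGMA) clustering with deterministic order.

    Returns (linkage matrix, per-sample flat labels at ``n_clusters``).
    """
    n = len(dist.sample_ids)
    if n < 2:
        raise ValueError("need >= 2 samples to cluster")
    z = hierarchy.linkage(dist.condensed(), method="average")
    labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return z, pd.Series(labels, index=dist.sample_ids, name="cluster")


def cophenetic(dist: DistanceMatrix) -> np.ndarray:
    z = hierarchy.linkage(dist.condensed(), method="average")
    return hierarchy.cophenet(z)
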