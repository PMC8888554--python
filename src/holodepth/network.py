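"""Consensus positive co-occurrence network over ASVs.

Five association estimators — Pearson, Spearman, SparCC (compositional
log-ratio basis correlations), local similarity (maximal aligned-run
statistic on depth-ordered normal scores) and a normalized-mutual-
information grid coefficient (MIC-style) — each produce a symmetric
statistic matrix and two-sided permutation/bootstrap p-values. The
consensus keeps an edge when at least four estimators call it
significant (p <= 0.05) and every calling estimator sees a positive
association.

Null p-values for the pairwise estimators come from rounds in which
every ASV's sample vector is permuted independently, so each pair's
relative permutation is uniform while one round prices the whole
matrix. SparCC follows its original formulation: null data sets shuffle
each ASV's counts independently and the two-sided p compares basis-
correlation magnitudes (add-one estimator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import normal_scores_rows, spawn_rng
from .tables import AsvTable

DEFAULT_MIN_SAMPLES = 3
DEFAULT_P_MAX = 0.05
DEFAULT_MIN_VOTES = 4
METHODS = ("pearson", "spearman", "sparcc", "local_similarity", "mic")


# ------------------------------------------------------------- preflight

def prevalence_filter(
    asv_table: AsvTable, min_samples: int = DEFAULT_MIN_SAMPLES
) -> tuple[AsvTable, float, pd.Series]:
    """Drop ASVs present in fewer than ``min_samples`` samples.

    Returns the filtered table, its sparsity (zero-cell fraction) and
    per-ASV N_eff (the number of samples in which each ASV is present —
    the usual network-preflight interpretation).
    """
    present = (asv_table.data > 0).sum(axis=0)
    keep = present[present >= min_samples].index
    if len(keep) == 0:
        raise ValueError(
            f"no ASV present in >= {min_samples} samples; lower min_samples"
        )
    filtered = AsvTable(asv_table.data[keep], kind=asv_table.kind)
    values = filtered.data.to_numpy()
    sparsity = float((values == 0).mean())
    n_eff = (filtered.data > 0).sum(axis=0)
    n_eff.name = "n_eff"
    return filtered, sparsity, n_eff


# ---------------------------------------------------------- result object

@dataclass
class AssociationResult:
    method: str
    statistic: pd.DataFrame
    p: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.statistic.index)


def _as_frames(
    method: str, ids: list[str], stat: np.ndarray, p: np.ndarray, params: dict
) -> AssociationResult:
    np.fill_diagonal(stat, 1.0 if method != "local_similarity" else 0.0)
    np.fill_diagonal(p, 1.0)
    return AssociationResult(
        method=method,
        statistic=pd.DataFrame(stat, index=ids, columns=ids),
        p=pd.DataFrame(p, index=ids, columns=ids),
        params=params,
    )


def _pairwise_permutation_p(
    rows: np.ndarray,
    stat_fn,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation p for a full pairwise statistic matrix.

    Each round permutes every row independently; |perm stat| >= |obs|
    counts toward the add-one p of that pair.
    """
    obs = stat_fn(rows)
    hits = np.zeros_like(obs)
    m, n = rows.shape
    for _ in range(n_perm):
        permuted = np.empty_like(rows)
        for i in range(m):
            permuted[i] = rows[i, rng.permutation(n)]
        hits += np.abs(stat_fn(permuted)) >= np.abs(obs) - 1e-12
    p = (1.0 + hits) / (1.0 + n_perm)
    p[np.isnan(obs)] = np.nan
    return obs, p


# ------------------------------------------------- Pearson / Spearman

def _corr_matrix(rows: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    sd = np.sqrt((rc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (rc @ rc.T) / np.outer(sd, sd)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    return np.clip(c, -1.0, 1.0)


def correlation_assoc(
    asv_table: AsvTable,
    method: str = "pearson",
    n_perm: int = 100,
    seed: int = 0,
) -> AssociationResult:
    """Pairwise Pearson/Spearman correlations on relative abundances with
    permutation p-values. Constant ASVs get NaN (undefined) pairs."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    rel = asv_table.relative_abundance().data.to_numpy(dtype=float).T  # ASVs x samples
    if rel.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    rng = spawn_rng(seed, "assoc", method)

    if method == "spearman":
        from scipy.stats import rankdata

        def stat_fn(rows):
            return _corr_matrix(rankdata(rows, axis=1))

    else:
        stat_fn = _corr_matrix

    obs, p = _pairwise_permutation_p(rel, stat_fn, n_perm, rng)
    return _as_frames(
        method, asv_table.asv_ids, obs, p, {"n_perm": n_perm, "seed": seed}
    )


# ------------------------------------------------------------------ SparCC

def _sparcc_rho(fractions: np.ndarray, n_iterations: int, threshold: float) -> np.ndarray:
    """SparCC basis correlations from the log-ratio variation matrix,
    with iterative exclusion of the strongest correlated pairs."""
    logf = np.log(fractions)  # ASVs x samples
    d = logf.shape[0]
    # Variation matrix t_ij = var(log(x_i/x_j)).
    var_i = logf.var(axis=1, ddof=1)
    cov = np.cov(logf)
    t_mat = var_i[:, None] + var_i[None, :] - 2.0 * cov
    np.fill_diagonal(t_mat, 0.0)

    m = np.full((d, d), 1.0)
    np.fill_diagonal(m, d - 1.0)
    t_vec = t_mat.sum(axis=1)
    excluded = np.zeros((d, d), dtype=bool)

    def _solve() -> np.ndarray:
        omega = np.linalg.solve(m, t_vec)
        omega = np.maximum(omega, 1e-12)
        rho = (omega[:, None] + omega[None, :] - t_mat) / (
            2.0 * np.sqrt(np.outer(omega, omega))
        )
        return np.clip(rho, -1.0, 1.0)

    rho = _solve()
    excl_count = np.zeros(d, dtype=int)
    for _ in range(n_iterations):
        work = np.abs(rho.copy())
        np.fill_diagonal(work, 0.0)
        work[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(work), work.shape)
        if work[i, j] <= threshold:
            break
        # a component excluded from too many pairs makes the basis-variance
        # system singular; stop excluding through it
        if excl_count[i] >= d - 3 or excl_count[j] >= d - 3:
            break
        excluded[i, j] = excluded[j, i] = True
        excl_count[i] += 1
        excl_count[j] += 1
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] = m[j, i] = 0.0
        t_vec[i] -= t_mat[i, j]
        t_vec[j] -= t_mat[i, j]
        try:
            rho = _solve()
        except np.linalg.LinAlgError:
            break
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc_assoc(
    asv_table: AsvTable,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    n_bootstrap: int = 100,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> AssociationResult:
    """SparCC basis correlations with two-sided null-resampling p-values.

    A pseudocount is added to the counts before closure. Null data sets
    shuffle each ASV's counts independently across samples.
    """
    counts = asv_table.data.to_numpy(dtype=float).T  # ASVs x samples
    d, n = counts.shape
    if d < 4:
        raise ValueError(
            "SparCC needs >= 4 ASVs: the basis-variance system is "
            "underdetermined below that"
        )
    rng = spawn_rng(seed, "sparcc")

    def _rho_from_counts(c: np.ndarray) -> np.ndarray:
        frac = (c + pseudocount) / (c + pseudocount).sum(axis=0, keepdims=True)
        return _sparcc_rho(frac, n_iterations, exclusion_threshold)

    obs = _rho_from_counts(counts)
    hits = np.zeros_like(obs)
    for _ in range(n_bootstrap):
        null = np.empty_like(counts)
        for i in range(d):
            null[i] = counts[i, rng.permutation(n)]
        hits += np.abs(_rho_from_counts(null)) >= np.abs(obs) - 1e-12
    p = (1.0 + hits) / (1.0 + n_bootstrap)
    return _as_frames(
        "sparcc",
        asv_table.asv_ids,
        obs,
        p,
        {
            "n_iterations": n_iterations,
            "exclusion_threshold": exclusion_threshold,
            "n_bootstrap": n_bootstrap,
            "seed": seed,
            "pseudocount": pseudocount,
        },
    )


# -------------------------------------------------------- local similarity

def _max_subarray(products: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise maximal contiguous-sum and minimal contiguous-sum."""
    c = np.cumsum(products, axis=-1)
    zero = np.zeros(c.shape[:-1] + (1,))
    c = np.concatenate([zero, c], axis=-1)
    run_max = np.maximum.accumulate(c, axis=-1)[..., :-1]
    run_min = np.minimum.accumulate(c, axis=-1)[..., :-1]
    best_max = (c[..., 1:] - run_min).max(axis=-1)
    best_min = (c[..., 1:] - run_max).min(axis=-1)
    return best_max, best_min


def _ls_matrix_factory(max_delay: int):
    def stat_fn(rows: np.ndarray) -> np.ndarray:
        m, n = rows.shape
        iu, ju = np.triu_indices(m, 1)
        best = np.full(iu.size, -np.inf)
        sign = np.ones(iu.size)
        for delay in range(max_delay + 1):
            length = n - delay
            if length < 2:
                break
            for a, b in ((iu, ju), (ju, iu)) if delay > 0 else ((iu, ju),):
                prod = rows[a][:, : length] * rows[b][:, delay : delay + length]
                pos, neg = _max_subarray(prod)
                score = np.maximum(pos, -neg)
                s = np.where(pos >= -neg, 1.0, -1.0)
                better = score > best
                best = np.where(better, score, best)
                sign = np.where(better, s, sign)
        out = np.zeros((m, m))
        out[iu, ju] = out[ju, iu] = sign * best / n
        return out

    return stat_fn


def local_similarity_assoc(
    asv_table: AsvTable,
    depths: np.ndarray,
    max_delay: int = 0,
    n_perm: int = 100,
    seed: int = 0,
) -> AssociationResult:
    """Local similarity on depth-ordered, rank-normal-transformed series.

    The score is the maximal contiguous aligned-run sum of products of
    normal scores (delays up to ``max_delay``), normalized by n, signed
    by the optimal run. p-values by seeded permutation (two-sided on the
    magnitude).
    """
    depths = np.asarray(depths, dtype=float)
    rel = asv_table.relative_abundance().data.to_numpy(dtype=float).T
    if depths.size != rel.shape[1]:
        raise ValueError("depth ordering variable does not match the samples")
    order = np.argsort(depths, kind="stable")
    z = normal_scores_rows(rel[:, order])
    rng = spawn_rng(seed, "lsa")
    stat_fn = _ls_matrix_factory(max_delay)
    obs, p = _pairwise_permutation_p(z, stat_fn, n_perm, rng)
    return _as_frames(
        "local_similarity",
        asv_table.asv_ids,
        obs,
        p,
        {"max_delay": max_delay, "n_perm": n_perm, "seed": seed},
    )


# --------------------------------------------------------------------- MIC

def _ordinal_ranks(rows: np.ndarray) -> np.ndarray:
    """0-based ordinal ranks per row (ties broken by sample order)."""
    order = np.argsort(rows, axis=1, kind="stable")
    ranks = np.empty_like(order)
    m, n = rows.shape
    ranks[np.arange(m)[:, None], order] = np.arange(n)
    return ranks


def _mic_matrix_factory(n: int, grid_exponent: float):
    b = max(n**grid_exponent, 4.0)
    shapes = [
        (x, y)
        for x in range(2, int(b // 2) + 1)
        for y in range(2, int(b // x) + 1)
    ]

    def stat_fn(rows: np.ndarray) -> np.ndarray:
        m = rows.shape[0]
        iu, ju = np.triu_indices(m, 1)
        npairs = iu.size
        best = np.zeros(npairs)
        ranks = _ordinal_ranks(rows)
        codes = {k: (ranks * k) // n for k in {s for xy in shapes for s in xy}}
        for x, y in shapes:
            cx = codes[x][iu]
            cy = codes[y][ju]
            joint = cx * y + cy
            offset = np.arange(npairs)[:, None] * (x * y)
            counts = np.bincount(
                (joint + offset).ravel(), minlength=npairs * x * y
            ).reshape(npairs, x, y)
            pxy = counts / n
            px = pxy.sum(axis=2)
            py = pxy.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                mi = np.nansum(
                    pxy * (np.log(pxy) - np.log(px[:, :, None]) - np.log(py[:, None, :])),
                    axis=(1, 2),
                )
                hx = -np.nansum(px * np.log(px), axis=1)
                hy = -np.nansum(py * np.log(py), axis=1)
                norm = np.minimum(hx, hy)
                score = np.where(norm > 0, mi / norm, 0.0)
            best = np.maximum(best, np.clip(score, 0.0, 1.0))
        out = np.zeros((m, m))
        out[iu, ju] = out[ju, iu] = best
        return out

    return stat_fn


def mic_assoc(
    asv_table: AsvTable,
    grid_exponent: float = 0.6,
    n_perm: int = 100,
    seed: int = 0,
) -> AssociationResult:
    """Grid-based normalized mutual-information dependence (MIC-style).

    Maximum over grid shapes x*y <= n^grid_exponent of the mutual
    information of rank-equipartitioned axes, normalized by the smaller
    marginal entropy (so a noiseless functional relationship scores
    exactly 1 at any n). p-values by seeded permutation.
    """
    import warnings

    rel = asv_table.relative_abundance().data.to_numpy(dtype=float).T
    n = rel.shape[1]
    if n < 4:
        raise ValueError("MIC needs >= 4 samples")
    if n < 8:
        warnings.warn("MIC with < 8 samples is poorly resolved", stacklevel=2)
    rng = spawn_rng(seed, "mic")
    stat_fn = _mic_matrix_factory(n, grid_exponent)
    obs, p = _pairwise_permutation_p(rel, stat_fn, n_perm, rng)
    return _as_frames(
        "mic", asv_table.asv_ids, obs, p, {"grid_exponent": grid_exponent,
                                           "n_perm": n_perm, "seed": seed}
    )


# --------------------------------------------------------------- consensus

@dataclass
class ConsensusNetwork:
    graph: nx.Graph
    sparsity: float | None = None
    n_eff: pd.Series | None = None
    params: dict = field(default_factory=dict)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def edge_frame(self) -> pd.DataFrame:
        records = []
        for a, b, attrs in self.graph.edges(data=True):
            a, b = sorted([a, b])
            rec = {"asv_a": a, "asv_b": b, "votes": attrs["votes"]}
            rec.update({f"p_{m}": attrs["p"].get(m, np.nan) for m in METHODS})
            records.append(rec)
        cols = ["asv_a", "asv_b", "votes"] + [f"p_{m}" for m in METHODS]
        return pd.DataFrame(sorted(records, key=lambda r: (r["asv_a"], r["asv_b"])),
                            columns=cols)


def consensus(
    results: list[AssociationResult],
    p_max: float = DEFAULT_P_MAX,
    min_votes: int = DEFAULT_MIN_VOTES,
    sparsity: float | None = None,
    n_eff: pd.Series | None = None,
) -> ConsensusNetwork:
    """Vote the per-method results into the consensus positive network.

    An edge exists iff at least ``min_votes`` methods have p <= p_max
    for the pair AND the statistic is positive in every voting method.
    Isolated nodes are dropped.
    """
    ids = results[0].asv_ids
    for r in results[1:]:
        if r.asv_ids != ids:
            raise ValueError(f"ASV sets differ between methods ({r.method})")
    g = nx.Graph()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            votes = 0
            all_positive = True
            pvals = {}
            for r in results:
                p = float(r.p.iat[i, j])
                stat = float(r.statistic.iat[i, j])
                pvals[r.method] = p
                if not np.isnan(p) and p <= p_max:
                    votes += 1
                    if stat <= 0:
                        all_positive = False
            if votes >= min_votes and all_positive:
                g.add_edge(a, b, votes=votes, p=pvals)
    return ConsensusNetwork(
        graph=g,
        sparsity=sparsity,
        n_eff=n_eff,
        params={"p_max": p_max, "min_votes": min_votes,
                "methods": [r.method for r in results]},
    )
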