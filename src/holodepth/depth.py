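"""Depth-trend classification of ASVs and metabolite features.

Each variable's relative abundance (or signal intensity) is correlated
with sample depth; significant correlations (two-sided p <= alpha) are
classed "increasing"/"decreasing" by sign, non-significant ones
"increasing-trend"/"decreasing-trend". Benjamini-Hochberg adjusted
p-values are reported alongside. A Welch t-test compares each variable
above vs below the 1000 m water-mass split, and ASVs are classed
"common" when their mean relative abundance exceeds 0.25%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AsvTable, WATER_MASS_SPLIT_M

DEFAULT_ALPHA = 0.05
DEFAULT_COMMON_THRESHOLD = 0.0025


def _fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg over the defined (non-NaN) family."""
    out = np.full_like(p, np.nan, dtype=float)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def classify_depth_trends(
    matrix: pd.DataFrame,
    depths: np.ndarray,
    method: str = "pearson",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Correlate each variable (row) with depth and classify its trend.

    ``matrix`` is variables x samples. Returns a frame indexed by
    variable id with columns r, p, p_fdr, trend_class and
    mean_abundance. Constant variables get class "none" with NaN
    statistics and are excluded from the FDR family.
    """
    depths = np.asarray(depths, dtype=float)
    if matrix.shape[1] != depths.size:
        raise ValueError(
            f"matrix has {matrix.shape[1]} samples but {depths.size} depths"
        )
    if depths.size < 3:
        raise ValueError("need >= 3 samples")
    if not np.isfinite(depths).all():
        raise ValueError("depths must be finite")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")

    values = matrix.to_numpy(dtype=float)
    n = depths.size
    if method == "spearman":
        x = stats.rankdata(depths)
        y = stats.rankdata(values, axis=1)
    else:
        x = depths
        y = values

    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum(axis=1))
    constant = sy == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / (sy * sx)
    r = np.clip(r, -1.0, 1.0)
    r[constant] = np.nan
    # Two-sided p from the t transform of r at n-2 df.
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[constant] = np.nan

    trend = np.where(
        np.isnan(r),
        "none",
        np.where(
            r > 0,
            np.where(p <= alpha, "increasing", "increasing-trend"),
            np.where(p <= alpha, "decreasing", "decreasing-trend"),
        ),
    )
    trend[(~np.isnan(r)) & (r == 0)] = "none"

    return pd.DataFrame(
        {
            "r": r,
            "p": p,
            "p_fdr": _fdr(p),
            "trend_class": trend,
            "mean_abundance": values.mean(axis=1),
        },
        index=matrix.index,
    )


def water_mass_ttest(
    matrix: pd.DataFrame,
    depths: np.ndarray,
    split: float = WATER_MASS_SPLIT_M,
) -> pd.DataFrame:
    """Welch t-test per variable, shallow (depth <= split) vs deep.

    Returns a frame with group means, t, p and BH-adjusted p. Variables
    constant across all samples are flagged (NaN) and excluded from the
    FDR family.
    """
    depths = np.asarray(depths, dtype=float)
    if matrix.shape[1] != depths.size:
        raise ValueError("matrix columns and depths differ in length")
    shallow = depths <= split
    n_sh, n_dp = int(shallow.sum()), int((~shallow).sum())
    if n_sh < 2 or n_dp < 2:
        raise ValueError(
            f"both depth groups need >= 2 samples (shallow={n_sh}, deep={n_dp})"
        )
    values = matrix.to_numpy(dtype=float)
    a, b = values[:, shallow], values[:, ~shallow]
    constant = values.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    t[constant] = np.nan
    p[constant] = np.nan
    return pd.DataFrame(
        {
            "mean_shallow": a.mean(axis=1),
            "mean_deep": b.mean(axis=1),
            "t": t,
            "p": p,
            "p_fdr": _fdr(p),
        },
        index=matrix.index,
    )


@dataclass
class CommonAsvSummary:
    common_ids: list[str]
    read_fraction: float


def classify_common(
    asv_table: AsvTable, threshold: float = DEFAULT_COMMON_THRESHOLD
) -> CommonAsvSummary:
    """ASVs whose mean relative abundance strictly exceeds ``threshold``.

    Also reports the fraction of total reads those common ASVs represent.
    """
    rel = asv_table.relative_abundance().data
    mean_rel = rel.mean(axis=0)
    common = list(mean_rel.index[mean_rel > threshold])
    counts = asv_table.data
    total = counts.to_numpy().sum()
    read_fraction = float(counts[common].to_numpy().sum() / total) if total > 0 else 0.0
    return CommonAsvSummary(common_ids=common, read_fraction=read_fraction)


@dataclass
class DepthResponseSummary:
    n_increasing: int
    n_decreasing: int
    fraction_responsive: float
    mean_abundance_responsive: float


def summarize_depth_response(
    results: pd.DataFrame, asv_table: AsvTable
) -> DepthResponseSummary:
    """Counts of significant increasers/decreasers, their fraction of all
    ASVs, and the mean per-sample relative abundance they represent."""
    if not set(results.index) <= set(asv_table.asv_ids):
        raise ValueError("trend results contain ids absent from the ASV table")
    inc = results.index[results["trend_class"] == "increasing"]
    dec = results.index[results["trend_class"] == "decreasing"]
    responsive = list(inc) + list(dec)
    rel = asv_table.relative_abundance().data
    mean_abund = float(rel[responsive].sum(axis=1).mean()) if responsive else 0.0
    n_total = len(results)
    return DepthResponseSummary(
        n_increasing=len(inc),
        n_decreasing=len(dec),
        fraction_responsive=len(responsive) / n_total if n_total else 0.0,
        mean_abundance_responsive=mean_abund,
    )
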