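"""Shared numerical helpers: seeded RNG streams and permutation p-values."""

from __future__ import annotations

import zlib
from itertools import permutations as _iter_permutations

import numpy as np


def spawn_rng(seed, *keys) -> np.random.Generator:
    """Derive an independent Generator from an integer seed and string keys.

    Every stochastic routine in the package draws from a stream produced
    here, so one pipeline seed determines every downstream draw while
    stages remain statistically independent of each other. Keys are
    hashed with CRC32 (stable across processes, unlike ``hash``).
    """
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def add_one_p(n_as_extreme: int, n_perm: int) -> float:
    """Permutation p with the add-one estimator (1+B)/(1+N); never zero."""
    return (1.0 + n_as_extreme) / (1.0 + n_perm)


def exhaustive_permutations(n: int):
    """All n! index permutations as an iterator of tuples (identity included)."""
    return _iter_permutations(range(n))


def rankdata_rows(x: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis (ties averaged), vectorised."""
    from scipy.stats import rankdata

    return rankdata(x, axis=-1)


def normal_scores_rows(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (van der Waerden) transform per row."""
    from scipy.stats import norm

    n = x.shape[-1]
    return norm.ppf(rankdata_rows(x) / (n + 1.0))


def check_square_symmetric(d: np.ndarray, name: str = "distance matrix") -> None:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square, got shape {d.shape}")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError(f"{name} must have a zero diagonal")
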