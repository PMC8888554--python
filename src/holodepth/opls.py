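"""Orthogonal projections to latent structures (OPLS) regression.

Single-response OPLS splits predictor variance into one component
predictive of the response (here: sample depth) and ``n_ortho``
components orthogonal to it. Model quality is summarised by R2X (X
variance captured, predictive + orthogonal), R2Y (training fit), the
k-fold cross-validated Q2 and its permutation p-value pQ2; per-feature
importance by VIP scores whose squared values average to 1.

The quality gates follow common chemometric practice for depth models:
reject when pQ2 > 0.05 (overfitting), call "good" when R2X > 0.9 and
Q2 > 0.5.

Numerics: X is mean-centred and unit-variance scaled (constant columns
are centred only); orthogonal components are extracted iteratively by
deflating X with the response-orthogonal part of the loading, then one
predictive component is computed on the deflated matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import add_one_p, spawn_rng

DEFAULT_R2X_MIN = 0.9
DEFAULT_Q2_MIN = 0.5
DEFAULT_PQ2_MAX = 0.05
DEFAULT_K_FOLD = 7
DEFAULT_N_PERM = 200


@dataclass
class OplsModel:
    """Fitted single-response OPLS model."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    w_pred: np.ndarray
    p_pred: np.ndarray
    q_pred: float
    t_pred: np.ndarray
    w_ortho: np.ndarray  # (n_ortho, p)
    p_ortho: np.ndarray
    t_ortho: np.ndarray  # (n_ortho, n)
    r2x: float
    r2y: float
    q2: float | None = None
    pq2: float | None = None
    vip: np.ndarray | None = None
    feature_ids: list[str] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_ortho(self) -> int:
        return self.w_ortho.shape[0]

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        """Predictive scores for new samples (orthogonal variation removed)."""
        x = (np.asarray(x_new, dtype=float) - self.x_mean) / self.x_scale
        for a in range(self.n_ortho):
            t_o = x @ self.w_ortho[a]
            x = x - np.outer(t_o, self.p_ortho[a])
        return x @ self.w_pred

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        return self.transform(x_new) * self.q_pred + self.y_mean


def _scale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns: centre only
    return (x - mean) / sd, mean, sd


def fit_opls(
    x: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 1,
    feature_ids: list[str] | None = None,
) -> OplsModel:
    """Fit an OPLS model with one predictive and ``n_ortho`` orthogonal
    components.

    With ``n_ortho=0`` this reduces exactly to single-component PLS1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be samples x features")
    n, p = x.shape
    if n < 4:
        raise ValueError("need >= 4 samples")
    if y.shape != (n,):
        raise ValueError("y length must match the number of samples")
    if np.isnan(x).all(axis=0).any():
        raise ValueError("x contains an all-missing feature")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to model")
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if n_ortho >= rank:
        raise ValueError(f"n_ortho={n_ortho} must be < rank(X)={rank}")

    xs, x_mean, x_scale = _scale(x)
    y_mean = float(y.mean())
    yc = y - y_mean
    ss_x_total = (xs**2).sum()

    xd = xs.copy()
    w_orthos, p_orthos, t_orthos = [], [], []
    for _ in range(n_ortho):
        w = xd.T @ yc
        w /= np.linalg.norm(w)
        t = xd @ w
        p_load = xd.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no response-orthogonal structure left
        w_o /= norm
        t_o = xd @ w_o
        p_o = xd.T @ t_o / (t_o @ t_o)
        xd = xd - np.outer(t_o, p_o)
        w_orthos.append(w_o)
        p_orthos.append(p_o)
        t_orthos.append(t_o)

    w = xd.T @ yc
    w /= np.linalg.norm(w)
    t = xd @ w
    p_load = xd.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))

    y_hat = t * q
    r2y = 1.0 - ((yc - y_hat) ** 2).sum() / (yc**2).sum()
    ss_pred = (np.outer(t, p_load) ** 2).sum()
    ss_ortho = sum((np.outer(t_o, p_o) ** 2).sum()
                   for t_o, p_o in zip(t_orthos, p_orthos))
    r2x = (ss_pred + ss_ortho) / ss_x_total

    n_o = len(w_orthos)
    model = OplsModel(
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        w_pred=w,
        p_pred=p_load,
        q_pred=q,
        t_pred=t,
        w_ortho=np.array(w_orthos).reshape(n_o, p),
        p_ortho=np.array(p_orthos).reshape(n_o, p),
        t_ortho=np.array(t_orthos).reshape(n_o, n),
        r2x=float(r2x),
        r2y=float(r2y),
        feature_ids=feature_ids,
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: OplsModel) -> np.ndarray:
    """Variable influence on projection for the predictive component.

    With a single predictive component the sum-of-squares weighting
    cancels and VIP_j = sqrt(p) * |w_j| with ||w|| = 1, so mean(VIP^2)
    is identically 1.
    """
    if model.w_pred is None:
        raise ValueError("model is not fitted")
    p = model.w_pred.size
    return np.sqrt(p) * np.abs(model.w_pred)


def _fold_assignment(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded partition into k near-equal folds (deterministic for k=n)."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k == n:
        order = np.arange(n)  # leave-one-out: seed-free deterministic order
    else:
        order = spawn_rng(seed, "cv_folds").permutation(n)
    return [order[i::k] for i in range(k)]


def cross_validated_q2(
    x: np.ndarray,
    y: np.ndarray,
    k: int = DEFAULT_K_FOLD,
    n_ortho: int = 1,
    seed: int = 0,
    folds: list[np.ndarray] | None = None,
) -> float:
    """k-fold cross-validated Q2 = 1 - PRESS/TSS.

    Folds come from a seeded shuffle; centring/scaling are re-estimated
    inside each training fold. TSS uses the training-fold mean as the
    null prediction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if folds is None:
        folds = _fold_assignment(n, k, seed)
    press = 0.0
    tss = 0.0
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        model = fit_opls(x[mask], y[mask], n_ortho=n_ortho)
        pred = model.predict(x[test_idx])
        press += ((y[test_idx] - pred) ** 2).sum()
        tss += ((y[test_idx] - y[mask].mean()) ** 2).sum()
    return 1.0 - press / tss


def permutation_pq2(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    k: int = DEFAULT_K_FOLD,
    n_ortho: int = 1,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for Q2 (and the observed Q2).

    pQ2 = (1 + #{Q2_perm >= Q2_obs}) / (1 + n_perm), with the response
    permuted each round and the fold assignment held fixed.
    """
    import warnings

    if n_perm < 20:
        warnings.warn("n_perm < 20: pQ2 resolution is too coarse", stacklevel=2)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = _fold_assignment(x.shape[0], k, seed)
    q2_obs = cross_validated_q2(x, y, k=k, n_ortho=n_ortho, folds=folds)
    rng = spawn_rng(seed, "pq2")
    hits = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        if np.ptp(yp) == 0:
            continue
        q2_p = cross_validated_q2(x, yp, k=k, n_ortho=n_ortho, folds=folds)
        if q2_p >= q2_obs - 1e-12:
            hits += 1
    return add_one_p(hits, n_perm), q2_obs


def evaluate_model(
    model: OplsModel,
    r2x_min: float = DEFAULT_R2X_MIN,
    q2_min: float = DEFAULT_Q2_MIN,
    pq2_max: float = DEFAULT_PQ2_MAX,
) -> str:
    """Classify a model as "rejected", "acceptable" or "good".

    Rejected iff pQ2 > pq2_max (overfitting); good iff not rejected and
    R2X > r2x_min and Q2 > q2_min; otherwise acceptable.
    """
    if model.q2 is None or model.pq2 is None:
        raise ValueError("model needs Q2 and pQ2 before evaluation")
    if model.pq2 > pq2_max:
        return "rejected"
    if model.r2x > r2x_min and model.q2 > q2_min:
        return "good"
    return "acceptable"


def fit_opls_with_validation(
    x: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 1,
    k: int = DEFAULT_K_FOLD,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    feature_ids: list[str] | None = None,
) -> OplsModel:
    """Fit + cross-validate + permutation-test in one call."""
    model = fit_opls(x, y, n_ortho=n_ortho, feature_ids=feature_ids)
    model.pq2, model.q2 = permutation_pq2(
        x, y, n_perm=n_perm, k=k, n_ortho=n_ortho, seed=seed
    )
    model.meta["verdict"] = evaluate_model(model)
    return model
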