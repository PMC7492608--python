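"""Fuzzy c-means clustering with a compactness/separation validity index.

FCM assigns each point a membership in every cluster according to its
distance from the cluster centers and alternates membership and center
updates until convergence.  The validity index used to choose the cluster
count is the ratio of within-cluster fuzzy scatter (normalized per cluster
by its fuzzy cardinality) to the minimal squared separation between centers;
smaller is better, and its minimum over candidate counts selects the count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["fcm_cluster", "fcm_objective", "validity_index", "select_fcm_clusters", "FCMResult"]


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


@dataclass
class FCMResult:
    memberships: np.ndarray  # (n, c), rows sum to 1
    centers: np.ndarray  # (c, d)
    objective: float
    n_iter: int

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def _update_memberships(X: np.ndarray, C: np.ndarray, m: float) -> np.ndarray:
    d = np.linalg.norm(X[:, None, :] - C[None, :, :], axis=2)
    zero = d < 1e-12
    d = np.maximum(d, 1e-12)
    U = 1.0 / np.sum((d[:, :, None] / d[:, None, :]) ** (2.0 / (m - 1.0)), axis=2)
    # points coinciding with a center get hard membership there
    hit = zero.any(axis=1)
    if hit.any():
        U[hit] = 0.0
        U[hit, np.argmax(zero[hit], axis=1)] = 1.0
    return U


def fcm_objective(X: np.ndarray, U: np.ndarray, C: np.ndarray, m: float = 2.0) -> float:
    d2 = np.linalg.norm(X[:, None, :] - C[None, :, :], axis=2) ** 2
    return float(np.sum(U**m * d2))


def fcm_cluster(
    X: np.ndarray,
    c: int,
    m: float = 2.0,
    seed: int | np.random.Generator = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> FCMResult:
    """Fuzzy c-means by alternating optimization, best of ``n_init`` starts.

    Centers initialize on distinct data points; convergence is a center shift
    below ``tol``.  Runs ending with (near-)coincident centers reinitialize
    up to 10 extra times before failing.
    """
    X = _as_matrix(X)
    if X.ndim != 2:
        raise ValueError("X must be (n, d)")
    n = len(X)
    if c < 2 or n <= c:
        raise ValueError("need c >= 2 and more points than clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = max(np.linalg.norm(X.max(0) - X.min(0)), 1e-12)
    best: FCMResult | None = None
    for _ in range(n_init):
        for _attempt in range(10):
            C = X[rng.choice(n, c, replace=False)].astype(float)
            C += rng.normal(0, 1e-9 * scale, C.shape)  # break exact duplicates
            it = 0
            for it in range(1, max_iter + 1):
                U = _update_memberships(X, C, m)
                Um = U.T**m
                Cn = (Um @ X) / np.maximum(Um.sum(axis=1, keepdims=True), 1e-300)
                shift = float(np.max(np.abs(Cn - C)))
                C = Cn
                if shift < tol:
                    break
            U = _update_memberships(X, C, m)
            dC = np.linalg.norm(C[:, None] - C[None], axis=2)
            np.fill_diagonal(dC, np.inf)
            if dC.min() > 1e-9 * scale:
                break
        else:
            raise RuntimeError("FCM kept collapsing to coincident centers")
        res = FCMResult(memberships=U, centers=C, objective=fcm_objective(X, U, C, m), n_iter=it)
        if best is None or res.objective < best.objective:
            best = res
    return best


def validity_index(X: np.ndarray, U: np.ndarray, C: np.ndarray, m: float = 2.0) -> float:
    """Within/between cluster validity ratio; smaller is better.

    within = sum_k (sum_i u_ik^m ||x_i - v_k||^2) / (sum_i u_ik), i.e. each
    cluster's fuzzy scatter normalized by its fuzzy cardinality; between =
    min_{j != k} ||v_j - v_k||^2.  Identical centers give +inf.
    """
    X = _as_matrix(X)
    d2 = np.linalg.norm(X[:, None, :] - C[None, :, :], axis=2) ** 2
    card = U.sum(axis=0)
    if np.any(card <= 0):
        return np.inf
    within = float((((U**m) * d2).sum(axis=0) / card).sum())
    sep = np.linalg.norm(C[:, None] - C[None], axis=2) ** 2
    np.fill_diagonal(sep, np.inf)
    s = float(sep.min())
    if s <= 0:
        return np.inf
    return within / s


def select_fcm_clusters(
    X: np.ndarray,
    c_range: tuple[int, int] = (2, 10),
    m: float = 2.0,
    seed: int = 0,
) -> tuple[int, dict[int, float], dict[int, FCMResult]]:
    """Fit FCM over a range of counts; return (selected count minimizing the
    validity index, index curve, fits)."""
    curve: dict[int, float] = {}
    fits: dict[int, FCMResult] = {}
    for c in range(c_range[0], c_range[1] + 1):
        if c >= len(_as_matrix(X)):
            break
        res = fcm_cluster(X, c, m=m, seed=seed)
        fits[c] = res
        curve[c] = validity_index(_as_matrix(X), res.memberships, res.centers, m)
    selected = min(curve, key=curve.get)
    return selected, curve, fits
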