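"""Joint-velocity matrices with controllable movement complexity, plus
head-acceleration traces.

Complexity is targeted by giving the latent components a geometric
eigenvalue profile lambda_i = r^i and solving the decay ratio r by bisection
so that the entropy-based complexity statistic of the generated sample
covariance hits the target.  Head acceleration is smoothed broadband noise,
generated independently of the EEG so it cannot explain PMBR dynamics.
"""

from __future__ import annotations

import numpy as np

from ..behavior import manipulative_complexity

__all__ = ["generate_joint_velocities", "generate_head_acceleration"]


def _sample_for_ratio(Z: np.ndarray, Q: np.ndarray, log_r: float) -> np.ndarray:
    n_joints = Z.shape[1]
    lam = np.exp(log_r * np.arange(n_joints))
    return (Z * np.sqrt(lam)) @ Q


def generate_joint_velocities(
    target_C: float,
    n_joints: int,
    n_samples: int,
    rng: np.random.Generator,
    tol: float = 0.005,
) -> np.ndarray:
    """(n_samples x n_joints) velocity matrix whose sample complexity is
    within ±0.02 of ``target_C`` (bisection tolerance 0.005).

    ``target_C`` = 1 requests equal latent variances; at finite sample sizes
    the sample statistic then sits slightly below 1 (eigenvalue spread), the
    closest any data can come to the upper endpoint.
    """
    if not 0.0 <= target_C <= 1.0:
        raise ValueError("target complexity must lie in [0, 1]")
    if n_joints < 2 or n_samples <= n_joints:
        raise ValueError("need n_joints >= 2 and more samples than joints")
    Z = rng.standard_normal((n_samples, n_joints))
    Q, _ = np.linalg.qr(rng.standard_normal((n_joints, n_joints)))

    lo, hi = -12.0, 0.0  # log decay ratio
    c_hi = manipulative_complexity(_sample_for_ratio(Z, Q, hi))
    if target_C >= c_hi:
        return _sample_for_ratio(Z, Q, hi)
    c_lo = manipulative_complexity(_sample_for_ratio(Z, Q, lo))
    if target_C <= c_lo:
        return _sample_for_ratio(Z, Q, lo)
    for _ in range(60):
        mid = (lo + hi) / 2.0
        c_mid = manipulative_complexity(_sample_for_ratio(Z, Q, mid))
        if abs(c_mid - target_C) < tol:
            return _sample_for_ratio(Z, Q, mid)
        if c_mid < target_C:
            lo = mid
        else:
            hi = mid
    return _sample_for_ratio(Z, Q, (lo + hi) / 2.0)


def generate_head_acceleration(
    n_trials: int,
    n_samples: int,
    rng: np.random.Generator,
    scale: float = 1.0,
    smooth: int = 25,
) -> np.ndarray:
    """Per-trial head-acceleration traces (m/s^2), independent of the EEG."""
    if n_trials < 1 or n_samples < smooth:
        raise ValueError("need at least one trial and more samples than the smoothing window")
    from scipy.ndimage import uniform_filter1d

    x = rng.standard_normal((n_trials, n_samples))
    out = uniform_filter1d(x, smooth, axis=1, mode="nearest")
    return scale * out
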