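"""Skill-learning metrics computed from the per-trial directional errors,
joint-velocity kinematics and head-acceleration traces.

Metrics follow the motor-learning literature: block learning curves of mean
absolute error; a learning rate normalizing the plateau improvement by the
initial error; intertrial variability (block SD of signed errors) and its
decay; mean trial-to-trial change; lag-1 autocorrelation of the signed error
series over session halves (short-series ACF estimates are biased, hence
halves of 150 trials rather than blocks); and manipulative complexity, a
[0, 1] entropy summary of how evenly variance spreads over the principal
components of the joint velocities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "learning_curve",
    "learning_rate",
    "intertrial_variability",
    "variability_decay",
    "trial_to_trial_change",
    "acf1",
    "acf1_halves",
    "manipulative_complexity",
    "head_movement_summary",
]


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    need = {"trial", "block", "error_deg"}
    if not need.issubset(records.columns):
        raise ValueError(f"records table must have columns {sorted(need)}")
    return records.sort_values("trial")


def learning_curve(records: pd.DataFrame) -> pd.Series:
    """Per-block mean absolute directional error (deg), indexed by block."""
    rec = _check_records(records)
    if rec["error_deg"].isna().any():
        rec = rec.dropna(subset=["error_deg"])
    curve = rec.groupby("block")["error_deg"].apply(lambda e: np.abs(e).mean())
    if (rec.groupby("block").size() < 1).any():
        raise ValueError("empty block in records")
    return curve


def learning_rate(
    records: pd.DataFrame,
    first_block: int = 1,
    plateau_trials: tuple[int, int] = (201, 300),
) -> float:
    """(E_first - E_plateau) / E_first.

    E_first is the mean absolute error over the first block; E_plateau pools
    the plateau trials (201-300 by default).  Negative when performance
    worsens; NaN when the initial error is zero.
    """
    rec = _check_records(records).dropna(subset=["error_deg"])
    e_first = np.abs(rec.loc[rec["block"] == first_block, "error_deg"]).mean()
    plateau = rec[(rec["trial"] >= plateau_trials[0]) & (rec["trial"] <= plateau_trials[1])]
    e_plat = np.abs(plateau["error_deg"]).mean()
    if not np.isfinite(e_first) or e_first == 0:
        return np.nan
    return float((e_first - e_plat) / e_first)


def intertrial_variability(records: pd.DataFrame) -> pd.Series:
    """Per-block sample SD (ddof=1) of the signed directional error."""
    rec = _check_records(records).dropna(subset=["error_deg"])
    sizes = rec.groupby("block").size()
    if (sizes < 2).any():
        raise ValueError("intertrial variability needs >= 2 trials per block")
    return rec.groupby("block")["error_deg"].std(ddof=1)


def variability_decay(
    records: pd.DataFrame,
    first_block: int = 1,
    plateau_trials: tuple[int, int] = (201, 300),
) -> float:
    """SD(first block) - SD(pooled plateau trials), in degrees."""
    rec = _check_records(records).dropna(subset=["error_deg"])
    sd_first = rec.loc[rec["block"] == first_block, "error_deg"].std(ddof=1)
    plateau = rec[(rec["trial"] >= plateau_trials[0]) & (rec["trial"] <= plateau_trials[1])]
    return float(sd_first - plateau["error_deg"].std(ddof=1))


def trial_to_trial_change(records: pd.DataFrame) -> pd.Series:
    """Per-block mean |e_t - e_{t-1}| over within-block consecutive pairs."""
    rec = _check_records(records).dropna(subset=["error_deg"])

    def _mean_abs_diff(g: pd.DataFrame) -> float:
        if len(g) < 2:
            raise ValueError("trial-to-trial change needs >= 2 trials per block")
        return float(np.abs(np.diff(g["error_deg"].to_numpy())).mean())

    return rec.groupby("block").apply(_mean_abs_diff, include_groups=False)


def acf1(x: np.ndarray) -> float:
    """Lag-1 autocorrelation: Pearson correlation of (e_t, e_{t+1}) pairs."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("ACF(1) needs at least 3 samples")
    a, b = x[:-1], x[1:]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def acf1_halves(records: pd.DataFrame) -> tuple[float, float, float]:
    """ACF(1) over the first and second halves of the session and the decay
    (first minus second).  Halves split the trial-sorted signed error series."""
    rec = _check_records(records)
    e = rec["error_deg"].to_numpy()
    n = len(e)
    first, second = e[: n // 2], e[n // 2 :]
    a1, a2 = acf1(first), acf1(second)
    return a1, a2, a1 - a2


def manipulative_complexity(velocities: np.ndarray) -> float:
    """Entropy-based movement complexity C in [0, 1].

    Eigen-decomposes the sample covariance of the (samples x joints) velocity
    matrix, normalizes the eigenvalues to proportions p_i and returns
    C = -sum p_i ln p_i / ln N.  C = 1 when all principal components
    contribute equally; C = 0 when a single component carries all variance.
    """
    V = np.asarray(velocities, dtype=float)
    if V.ndim != 2 or V.shape[0] <= V.shape[1]:
        raise ValueError("need a (samples x joints) matrix with more samples than joints")
    if V.shape[1] < 2:
        raise ValueError("need at least 2 joints")
    lam = np.linalg.eigvalsh(np.cov(V, rowvar=False))
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    p = lam / total
    nz = p > 0
    H = float(-(p[nz] * np.log(p[nz])).sum())
    return H / np.log(V.shape[1])


def head_movement_summary(
    accel: np.ndarray,
    times: np.ndarray,
    blocks: np.ndarray,
    window: tuple[float, float] = (0.0, 2.0),
) -> pd.DataFrame:
    """Per-trial peak |acceleration| in the post-offset window, block-averaged.

    ``accel`` is (n_trials, n_times) with ``times`` relative to movement
    offset; the window matches the PMBR search interval.
    """
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    w = (times >= window[0]) & (times <= window[1])
    if not w.any():
        raise ValueError("head-acceleration trace does not cover the PMBR window")
    peak = np.abs(accel[:, w]).max(axis=1)
    df = pd.DataFrame({"trial": np.arange(1, len(peak) + 1), "block": blocks, "peak_accel": peak})
    return df
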