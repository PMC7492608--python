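"""Synthetic overhead-camera ball tracks for single pool shots.

The cue ball rests at its start position, accelerates toward the target
ball at the programmed onset time, and the target ball departs shortly
afterwards along a straight line whose angle deviates from the pocket
direction by the programmed signed error (counterclockwise positive).  The
target's speed rises then decays (strike then friction), so the
peak-velocity sample the tracking analysis uses lies on the straight
departure line and the analysis recovers the programmed error.
"""

from __future__ import annotations

import numpy as np

from ..tracking import BallTrack, TableGeometry

__all__ = ["generate_ball_track"]


def _rotate(v: np.ndarray, deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def generate_ball_track(
    error_deg: float,
    onset_time: float,
    geometry: TableGeometry,
    sfreq: float = 200.0,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.2,
    start_time: float | None = None,
    duration: float = 3.0,
    cue_speed: float = 900.0,
    target_peak_speed: float = 1800.0,
    trial: int = 0,
) -> BallTrack:
    """Cue and target coordinate series (mm) for one shot.

    The track window starts 1 s before ``onset_time`` by default and spans
    ``duration`` seconds.  ``noise_sd`` adds isotropic measurement jitter.
    """
    if sfreq <= 0 or duration <= 0:
        raise ValueError("sampling rate and duration must be positive")
    rng = np.random.default_rng() if rng is None else rng
    t0 = onset_time - 1.0 if start_time is None else start_time
    n = int(round(duration * sfreq))
    time = t0 + np.arange(n) / sfreq

    cue_start = np.asarray(geometry.cue_start, float)
    tgt_start = np.asarray(geometry.target_start, float)

    # cue: at rest, then exponential-decay speed profile toward the target
    tau_c = 0.25
    dt_c = np.clip(time - onset_time, 0.0, None)
    disp_c = cue_speed * tau_c * (1.0 - np.exp(-dt_c / tau_c))
    gap = np.linalg.norm(tgt_start - cue_start) - geometry.ball_diameter
    disp_c = np.minimum(disp_c, gap)  # stops at contact
    dir_c = (tgt_start - cue_start) / np.linalg.norm(tgt_start - cue_start)
    cue = cue_start + disp_c[:, None] * dir_c

    # target: departs shortly after onset along the error-rotated pocket line
    depart = onset_time + 0.12
    pocket_dir = np.asarray(geometry.pocket, float) - tgt_start
    pocket_dir = pocket_dir / np.linalg.norm(pocket_dir)
    move_dir = _rotate(pocket_dir, error_deg)
    tau_r = 0.12
    tt = np.clip(time - depart, 0.0, None)
    speed = target_peak_speed * (tt / tau_r) * np.exp(1.0 - tt / tau_r)
    disp_t = np.concatenate(
        [[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2.0) / sfreq]
    )
    target = tgt_start + disp_t[:, None] * move_dir

    if noise_sd > 0:
        cue = cue + rng.normal(0.0, noise_sd, cue.shape)
        target = target + rng.normal(0.0, noise_sd, target.shape)
    return BallTrack(time=time, cue=cue, target=target, trial=trial)
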