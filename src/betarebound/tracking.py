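"""Ball-tracking analysis: shot onset, signed directional error, segmentation.

The experiment records overhead-camera positions (mm, ~200 Hz) of the white
cue ball and the red target ball on a pool table.  Movement onset is the
moment the cue-ball center leaves a 40 x 40 mm bounding box around its rest
position.  The per-shot directional error is the signed angle between the
target ball's departure direction (taken at its peak speed) and the direction
from its rest position to the pocket center, both measured relative to the
cue-to-target line.  Positive errors are counterclockwise of the pocket
direction; angles are wrapped to (-180, 180] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BallTrack",
    "TableGeometry",
    "NoShotError",
    "detect_onset",
    "peak_speed_sample",
    "directional_error",
    "segment_blocks",
    "build_trial_records",
]


class NoShotError(RuntimeError):
    """Raised when a track contains no detectable ball movement."""


@dataclass
class TableGeometry:
    """Physical layout of the shot, all coordinates in mm.

    The 48-mm cue ball rests inside a 40 x 40 mm axis-aligned bounding box
    (half-width 20 mm); leaving the box defines movement onset.
    """

    ball_diameter: float = 48.0
    box_half_width: float = 20.0
    cue_start: tuple[float, float] = (600.0, 200.0)
    target_start: tuple[float, float] = (600.0, 500.0)
    pocket: tuple[float, float] = (100.0, 1100.0)

    def __post_init__(self) -> None:
        if self.box_half_width <= 0:
            raise ValueError("bounding box half-width must be positive")
        if np.allclose(self.pocket, self.target_start):
            raise ValueError("pocket must be distinct from the target start")

    def to_dict(self) -> dict:
        return {
            "ball_diameter": self.ball_diameter,
            "box_half_width": self.box_half_width,
            "cue_start": list(self.cue_start),
            "target_start": list(self.target_start),
            "pocket": list(self.pocket),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TableGeometry":
        return cls(
            ball_diameter=d["ball_diameter"],
            box_half_width=d["box_half_width"],
            cue_start=tuple(d["cue_start"]),
            target_start=tuple(d["target_start"]),
            pocket=tuple(d["pocket"]),
        )


@dataclass
class BallTrack:
    """Time-stamped cue and target ball positions for one trial."""

    time: np.ndarray  # seconds, strictly increasing
    cue: np.ndarray  # (n, 2) mm
    target: np.ndarray  # (n, 2) mm
    trial: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cue = np.asarray(self.cue, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ValueError("track needs at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for arr in (self.cue, self.target):
            if arr.shape != (len(self.time), 2) or not np.all(np.isfinite(arr)):
                raise ValueError("positions must be finite (n, 2) arrays")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "time_s": self.time,
                "cue_x_mm": self.cue[:, 0],
                "cue_y_mm": self.cue[:, 1],
                "target_x_mm": self.target[:, 0],
                "target_y_mm": self.target[:, 1],
            }
        )


def tracks_to_csv(tracks: list[BallTrack], path: str | Path) -> None:
    pd.concat([t.to_frame() for t in tracks], ignore_index=True).to_csv(path, index=False)


def tracks_from_csv(path: str | Path) -> list[BallTrack]:
    df = pd.read_csv(path)
    out = []
    for trial, g in df.groupby("trial", sort=True):
        out.append(
            BallTrack(
                time=g["time_s"].to_numpy(),
                cue=g[["cue_x_mm", "cue_y_mm"]].to_numpy(),
                target=g[["target_x_mm", "target_y_mm"]].to_numpy(),
                trial=int(trial),
            )
        )
    return out


def detect_onset(track: BallTrack, geometry: TableGeometry) -> float:
    """Time the cue-ball center first leaves its bounding box.

    The box is axis-aligned and centered on the cue ball's initial position.
    Raises :class:`NoShotError` if the ball never leaves the box.
    """
    origin = track.cue[0]
    outside = np.max(np.abs(track.cue - origin), axis=1) > geometry.box_half_width
    idx = np.flatnonzero(outside)
    if idx.size == 0:
        raise NoShotError("cue ball never left its bounding box")
    return float(track.time[idx[0]])


def peak_speed_sample(positions: np.ndarray, smooth: int = 5) -> int:
    """Index of peak speed from a (n, 2) coordinate series.

    Positions are smoothed with a centered ``smooth``-sample moving average
    (25 ms at 200 Hz) before central finite differencing; ties break to the
    earliest sample.  Raises :class:`NoShotError` for a constant series.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 3:
        raise ValueError("need at least 3 samples of 2-D positions")
    kernel = np.ones(smooth) / smooth
    sm = np.column_stack(
        [np.convolve(np.pad(pos[:, j], smooth // 2, mode="edge"), kernel, "valid") for j in range(pos.shape[1])]
    )[: pos.shape[0]]
    vel = np.gradient(sm, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    smax = speed.max()
    if smax <= 1e-12:
        raise NoShotError("no movement in the position series")
    # ties (to floating tolerance) break to the earliest sample
    return int(np.flatnonzero(speed >= smax * (1.0 - 1e-9))[0])


def _signed_angle_deg(v: np.ndarray, reference: np.ndarray) -> float:
    """CCW-positive angle of ``v`` relative to ``reference``, in (-180, 180]."""
    ang = np.degrees(
        np.arctan2(v[1], v[0]) - np.arctan2(reference[1], reference[0])
    )
    ang = (ang + 180.0) % 360.0 - 180.0
    if ang == -180.0:
        ang = 180.0
    return float(ang)


def directional_error(
    track: BallTrack,
    geometry: TableGeometry,
    min_peak_speed: float = 50.0,
) -> float:
    """Signed directional error of the shot, in degrees.

    Both the target ball's departure angle (at its peak speed) and the pocket
    angle are measured relative to the straight line from cue start to target
    start; the error is their difference, wrapped to (-180, 180], with
    counterclockwise positive.  ``min_peak_speed`` (mm/s) is the movement
    floor below which the trial is declared a non-shot.
    """
    baseline = np.asarray(geometry.target_start) - np.asarray(geometry.cue_start)
    t_start = track.target[0]
    idx = peak_speed_sample(track.target)
    dt = np.median(np.diff(track.time))
    sm_speed = np.linalg.norm(np.gradient(track.target, axis=0)[idx]) / dt
    if sm_speed < min_peak_speed:
        raise NoShotError("target ball peak speed below movement floor")
    move_vec = track.target[idx] - t_start
    if np.linalg.norm(move_vec) <= 1e-9:
        raise NoShotError("target ball did not displace")
    pocket_vec = np.asarray(geometry.pocket) - t_start
    move_ang = _signed_angle_deg(move_vec, baseline)
    pocket_ang = _signed_angle_deg(pocket_vec, baseline)
    err = move_ang - pocket_ang
    err = (err + 180.0) % 360.0 - 180.0
    return 180.0 if err == -180.0 else float(err)


def segment_blocks(n_trials: int, set_size: int = 50, block_size: int = 25) -> pd.DataFrame:
    """1-based (trial, set, block) assignment for a session.

    A 300-trial session with sets of 50 and blocks of 25 yields 6 sets and 12
    blocks.  ``n_trials`` must divide evenly into blocks and ``set_size`` into
    ``block_size``.
    """
    if n_trials % block_size != 0:
        raise ValueError(
            f"{n_trials} trials do not divide into blocks of {block_size}"
        )
    if set_size % block_size != 0:
        raise ValueError(f"set size {set_size} is not a multiple of block size {block_size}")
    trial = np.arange(1, n_trials + 1)
    return pd.DataFrame(
        {
            "trial": trial,
            "set": (trial - 1) // set_size + 1,
            "block": (trial - 1) // block_size + 1,
        }
    )


def build_trial_records(
    tracks: list[BallTrack],
    geometry: TableGeometry,
    set_size: int = 50,
    block_size: int = 25,
) -> pd.DataFrame:
    """Per-trial table: trial, set, block, onset_s, error_deg.

    Trials with no detectable shot get NaN onset/error and usable=False.
    """
    seg = segment_blocks(len(tracks), set_size, block_size).set_index("trial")
    rows = []
    for i, track in enumerate(tracks, start=1):
        try:
            onset = detect_onset(track, geometry)
            err = directional_error(track, geometry)
            usable = True
        except NoShotError:
            onset, err, usable = np.nan, np.nan, False
        rows.append(
            {
                "trial": i,
                "set": int(seg.loc[i, "set"]),
                "block": int(seg.loc[i, "block"]),
                "onset_s": onset,
                "error_deg": err,
                "usable": usable,
            }
        )
    return pd.DataFrame(rows)
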