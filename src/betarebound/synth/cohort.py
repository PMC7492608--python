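"""Cohort assembly: one synthetic study with the structure the analysis assumes.

A default cohort has 30 subjects performing 300 self-paced pool shots (6 sets
of 50 trials, analyzed as 12 blocks of 25).  Sixteen subjects are programmed
as "increasers" (negative PMBR-error coupling, true correlations drawn from a
Gaussian with mean -0.40, SD 0.26 truncated to negative values) and fourteen
as "decreasers" (mean +0.47, SD 0.17, truncated positive).  Error-curve and
complexity defaults differ by group so the cohort reproduces the behavioral
signatures that separate error-based from reward-based learners: decreasers
show a steeper variability decay, larger early trial-to-trial changes and a
larger ACF(1) decay; increasers move with higher manipulative complexity.

Everything is reproducible from ``CohortConfig.seed``; each subject draws
from an independent child stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..tracking import BallTrack, TableGeometry, segment_blocks, tracks_to_csv
from ..edf import write_edf
from .errors import ErrorCurve, generate_error_series
from .coupling import draw_true_correlations, program_block_pmbr
from .eeg import EEGParams, calibrate_burst_mapping, generate_trial_epochs
from .balltrack import generate_ball_track
from .kinematics import generate_head_acceleration, generate_joint_velocities

__all__ = [
    "CouplingSpec",
    "ComplexityCurve",
    "CohortConfig",
    "SubjectData",
    "Cohort",
    "generate_subject",
    "generate_cohort",
]

GROUPS = ("increaser", "decreaser")


@dataclass(frozen=True)
class CouplingSpec:
    """Across-subject distribution of true PMBR-error correlations."""

    corr_mean: float
    corr_sd: float

    def __post_init__(self) -> None:
        if abs(self.corr_mean) >= 1 or self.corr_sd <= 0:
            raise ValueError("coupling needs |mean| < 1 and sd > 0")


@dataclass(frozen=True)
class ComplexityCurve:
    """Linear per-block manipulative-complexity targets."""

    initial_C: float
    final_C: float

    def __post_init__(self) -> None:
        if not (0 <= self.initial_C <= 1 and 0 <= self.final_C <= 1):
            raise ValueError("complexity targets must lie in [0, 1]")

    def block_targets(self, n_blocks: int) -> np.ndarray:
        return np.linspace(self.initial_C, self.final_C, n_blocks)


def _default_error_curves() -> dict[str, ErrorCurve]:
    return {
        "increaser": ErrorCurve(
            initial_bias=6.0, plateau_bias=1.35, initial_sd=4.0,
            plateau_sd=3.2, decay_constant=60.0, ar1_rho=0.18,
        ),
        "decreaser": ErrorCurve(
            initial_bias=10.0, plateau_bias=1.5, initial_sd=7.5,
            plateau_sd=3.0, decay_constant=18.0, ar1_rho=0.22,
        ),
    }


def _default_coupling() -> dict[str, CouplingSpec]:
    return {
        "increaser": CouplingSpec(corr_mean=-0.40, corr_sd=0.26),
        "decreaser": CouplingSpec(corr_mean=0.47, corr_sd=0.17),
    }


def _default_complexity() -> dict[str, ComplexityCurve]:
    return {
        "increaser": ComplexityCurve(initial_C=0.55, final_C=0.70),
        "decreaser": ComplexityCurve(initial_C=0.45, final_C=0.60),
    }


@dataclass
class CohortConfig:
    n_subjects: int = 30
    n_negative_coupling: int = 16  # number of increasers
    n_trials: int = 300
    set_size: int = 50
    block_size: int = 25
    sfreq_eeg: float = 256.0
    sfreq_track: float = 200.0
    error_curve: dict[str, ErrorCurve] = field(default_factory=_default_error_curves)
    coupling: dict[str, CouplingSpec] = field(default_factory=_default_coupling)
    complexity_curve: dict[str, ComplexityCurve] = field(default_factory=_default_complexity)
    pmbr_scale: float = 5.0  # SD of programmed block PMBR, % change units
    pmbr_offset: float = 21.0  # center of programmed block PMBR, % change
    eeg_snr: float = 2.0
    n_joints: int = 16
    kin_samples_per_block: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negative_coupling > self.n_subjects:
            raise ValueError("n_negative_coupling cannot exceed n_subjects")
        if self.n_trials % self.block_size != 0:
            raise ValueError("n_trials must divide into blocks")
        if self.set_size % self.block_size != 0:
            raise ValueError("set_size must divide into blocks")
        for d in (self.error_curve, self.coupling, self.complexity_curve):
            if set(d) != set(GROUPS):
                raise ValueError(f"per-group settings must cover {GROUPS}")

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_size

    def eeg_params(self) -> EEGParams:
        return EEGParams(sfreq=self.sfreq_eeg).with_snr(self.eeg_snr)

    def group_of(self, subject_index: int) -> str:
        return "increaser" if subject_index < self.n_negative_coupling else "decreaser"

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["error_curve"] = {g: asdict(v) for g, v in self.error_curve.items()}
        d["coupling"] = {g: asdict(v) for g, v in self.coupling.items()}
        d["complexity_curve"] = {g: asdict(v) for g, v in self.complexity_curve.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["error_curve"] = {g: ErrorCurve(**v) for g, v in d["error_curve"].items()}
        d["coupling"] = {g: CouplingSpec(**v) for g, v in d["coupling"].items()}
        d["complexity_curve"] = {
            g: ComplexityCurve(**v) for g, v in d["complexity_curve"].items()
        }
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SubjectData:
    subject_id: str
    group: str
    true_corr: float
    errors: np.ndarray  # programmed signed errors (deg), n_trials
    block_pmbr: np.ndarray  # programmed block PMBR values (%), n_blocks
    epochs: np.ndarray | None  # (n_trials, n_samples) µV
    offset_index: int  # movement-offset sample within each epoch
    events: pd.DataFrame  # trial, set, block, ball_onset_time_s (into recording)
    tracks: list[BallTrack] | None
    kinematics: list[np.ndarray] | None  # one (samples x joints) matrix per block
    complexity_targets: np.ndarray | None
    head_accel: np.ndarray | None  # (n_trials, n_samples) m/s^2, epoch-aligned


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectData]
    truth: pd.DataFrame


def _truth_row(config: CohortConfig, s: SubjectData) -> dict:
    row = {
        "subject": s.subject_id,
        "group": s.group,
        "true_corr": s.true_corr,
    }
    row.update({f"pmbr_b{b + 1}": v for b, v in enumerate(s.block_pmbr)})
    if s.complexity_targets is not None:
        row.update({f"complexity_b{b + 1}": v for b, v in enumerate(s.complexity_targets)})
    row.update({f"err_{k}": v for k, v in asdict(config.error_curve[s.group]).items()})
    return row


def generate_subject(
    config: CohortConfig,
    subject_index: int,
    rng: np.random.Generator,
    geometry: TableGeometry | None = None,
    with_eeg: bool = True,
    with_tracks: bool = True,
    with_kinematics: bool = True,
    with_head: bool = True,
) -> SubjectData:
    """Generate one subject's session given its own random stream."""
    geometry = TableGeometry() if geometry is None else geometry
    group = config.group_of(subject_index)
    params = config.eeg_params()
    seg = segment_blocks(config.n_trials, config.set_size, config.block_size)
    blocks = seg["block"].to_numpy()

    errors = generate_error_series(config.error_curve[group], config.n_trials, rng)
    block_abs_err = np.array(
        [np.abs(errors[blocks == b]).mean() for b in range(1, config.n_blocks + 1)]
    )
    true_corr = float(
        draw_true_correlations(
            config.coupling[group].corr_mean, config.coupling[group].corr_sd, 1, rng
        )[0]
    )
    block_pmbr = program_block_pmbr(
        true_corr, block_abs_err, config.pmbr_scale, rng, offset=config.pmbr_offset
    )

    epochs = None
    if with_eeg:
        cal = calibrate_burst_mapping(params)
        targets = np.clip(block_pmbr, cal.target_min, cal.target_max)
        amps = np.asarray(cal.amp_from_target(targets[blocks - 1]), dtype=float)
        epochs = generate_trial_epochs(amps, params, rng)

    events = pd.DataFrame(
        {
            "trial": seg["trial"],
            "set": seg["set"],
            "block": seg["block"],
            "ball_onset_time_s": (seg["trial"] - 1) * params.epoch_duration
            + params.offset_time,
        }
    )

    tracks = None
    if with_tracks:
        tracks = [
            generate_ball_track(
                float(errors[i]),
                onset_time=params.offset_time,
                geometry=geometry,
                sfreq=config.sfreq_track,
                rng=rng,
                trial=i + 1,
            )
            for i in range(config.n_trials)
        ]

    kinematics = None
    complexity_targets = None
    if with_kinematics:
        complexity_targets = config.complexity_curve[group].block_targets(config.n_blocks)
        kinematics = [
            generate_joint_velocities(
                float(c), config.n_joints, config.kin_samples_per_block, rng
            )
            for c in complexity_targets
        ]

    head = None
    if with_head:
        head = generate_head_acceleration(config.n_trials, params.n_samples, rng)

    return SubjectData(
        subject_id=f"sub-{subject_index + 1:02d}",
        group=group,
        true_corr=true_corr,
        errors=errors,
        block_pmbr=block_pmbr,
        epochs=epochs,
        offset_index=params.offset_index,
        events=events,
        tracks=tracks,
        kinematics=kinematics,
        complexity_targets=complexity_targets,
        head_accel=head,
    )


def subject_rngs(config: CohortConfig) -> list[np.random.Generator]:
    """One independent child stream per subject, derived from the config seed."""
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(child) for child in ss.spawn(config.n_subjects)]


def generate_cohort(
    config: CohortConfig | None = None,
    out_dir: str | Path | None = None,
    geometry: TableGeometry | None = None,
    **subject_kwargs,
) -> Cohort:
    """Generate a full cohort; optionally write it to ``out_dir``.

    On disk each subject gets an EDF recording (concatenated trial epochs,
    channel "C3"), an events CSV, ball-track CSV, per-block kinematics CSVs
    and a head-acceleration CSV; the cohort gets a truth table and the config
    as YAML.
    """
    config = CohortConfig() if config is None else config
    subjects = [
        generate_subject(config, i, rng, geometry=geometry, **subject_kwargs)
        for i, rng in enumerate(subject_rngs(config))
    ]
    truth = pd.DataFrame([_truth_row(config, s) for s in subjects])
    cohort = Cohort(config=config, subjects=subjects, truth=truth)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.config.to_yaml(out / "cohort_config.yaml")
    cohort.truth.to_csv(out / "truth.csv", index=False)
    for s in cohort.subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        if s.epochs is not None:
            write_edf(
                sdir / "eeg.edf",
                s.epochs.reshape(-1),
                cohort.config.sfreq_eeg,
                ch_name="C3",
            )
        s.events.to_csv(sdir / "events.csv", index=False)
        if s.tracks is not None:
            tracks_to_csv(s.tracks, sdir / "ball_tracks.csv")
        if s.kinematics is not None:
            kdir = sdir / "kinematics"
            kdir.mkdir(exist_ok=True)
            for b, mat in enumerate(s.kinematics, start=1):
                np.savetxt(kdir / f"block-{b:02d}.csv", mat, delimiter=",")
        if s.head_accel is not None:
            np.savetxt(sdir / "head_acceleration.csv", s.head_accel, delimiter=",")
    return out
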