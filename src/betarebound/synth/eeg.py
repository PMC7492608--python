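"""Single-channel synthetic EEG with a programmable post-movement beta burst.

Each 6-s trial epoch (movement offset fixed at 3 s) contains:

* 1/f "pink" broadband background, in microvolts;
* an ongoing ~20 Hz beta oscillation with slow amplitude modulation and a
  Gaussian event-related desynchronization (ERD) dip around the movement;
* a Gaussian-envelope beta burst (envelope SD 150 ms) peaking 0.3-0.8 s
  after movement offset — the PMBR.

Burst amplitude is not the same thing as the percent-change PMBR the
analysis pipeline extracts (the log/block normalization and the background
beta level intervene), so the mapping from a desired extracted PMBR to a
burst amplitude is established once by a calibration sweep: blocks of
constant-amplitude trials are pushed through the real extraction path, the
resulting curve is fit with the monotone 3-parameter model

    extracted(a) = c0 + c1 * ln(1 + (a / c2)^2),

and inverted analytically.  The sweep is deterministic (fixed internal seed)
and cached per parameter set within a process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EEGParams",
    "generate_trial_epochs",
    "generate_trial_eeg",
    "calibrate_burst_mapping",
    "BurstCalibration",
]


@dataclass(frozen=True)
class EEGParams:
    """Shape parameters of the synthetic EEG (amplitudes in µV, times in s)."""

    sfreq: float = 256.0
    epoch_duration: float = 6.0
    offset_time: float = 3.0  # movement offset within the epoch
    beta_freq: float = 20.0
    beta_amp: float = 6.0
    noise_amp: float = 3.0
    erd_depth: float = 0.4
    erd_width: float = 0.25
    erd_lead: float = 0.15  # ERD dip center precedes the offset by this much
    burst_delay: float = 0.55
    burst_delay_jitter: float = 0.05
    burst_width: float = 0.15  # envelope SD
    am_depth: float = 0.1
    am_freq: float = 0.3

    def __post_init__(self) -> None:
        if self.sfreq <= 0 or self.epoch_duration <= 0:
            raise ValueError("sampling rate and duration must be positive")
        if not 0 < self.offset_time < self.epoch_duration:
            raise ValueError("movement offset must lie inside the epoch")
        if self.offset_time + 2.0 > self.epoch_duration:
            raise ValueError("epoch must cover the 2-s post-offset search window")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.sfreq))

    @property
    def offset_index(self) -> int:
        return int(round(self.offset_time * self.sfreq))

    @property
    def snr(self) -> float:
        """Beta-oscillation amplitude over broadband noise RMS."""
        return self.beta_amp / self.noise_amp

    def with_snr(self, snr: float) -> "EEGParams":
        if snr <= 0:
            raise ValueError("snr must be positive")
        return replace(self, noise_amp=self.beta_amp / snr)


def _pink_noise(rng: np.random.Generator, n_trials: int, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise, one row per trial."""
    w = rng.standard_normal((n_trials, n))
    W = np.fft.rfft(w, axis=1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    x = np.fft.irfft(W / np.sqrt(f), n, axis=1)
    return x / x.std(axis=1, keepdims=True)


def generate_trial_epochs(
    burst_amps: np.ndarray, params: EEGParams, rng: np.random.Generator
) -> np.ndarray:
    """Synthesize one epoch per entry of ``burst_amps`` (µV); (n, N) output."""
    amps = np.atleast_1d(np.asarray(burst_amps, dtype=float))
    if np.any(amps < 0):
        raise ValueError("burst amplitudes must be nonnegative")
    n_trials, N = len(amps), params.n_samples
    t = np.arange(N) / params.sfreq
    x = params.noise_amp * _pink_noise(rng, n_trials, N)

    erd = 1.0 - params.erd_depth * np.exp(
        -0.5 * ((t - (params.offset_time - params.erd_lead)) / params.erd_width) ** 2
    )
    am_phase = rng.uniform(0, 2 * np.pi, (n_trials, 1))
    beta_phase = rng.uniform(0, 2 * np.pi, (n_trials, 1))
    am = 1.0 + params.am_depth * np.sin(2 * np.pi * params.am_freq * t + am_phase)
    x += (
        params.beta_amp
        * erd
        * am
        * np.cos(2 * np.pi * params.beta_freq * t + beta_phase)
    )

    centers = (
        params.offset_time
        + params.burst_delay
        + rng.normal(0.0, params.burst_delay_jitter, (n_trials, 1))
    )
    burst_phase = rng.uniform(0, 2 * np.pi, (n_trials, 1))
    env = np.exp(-0.5 * ((t - centers) / params.burst_width) ** 2)
    x += amps[:, None] * env * np.cos(2 * np.pi * params.beta_freq * t + burst_phase)
    return x


@dataclass(frozen=True)
class BurstCalibration:
    """Fitted monotone map between burst amplitude and extracted PMBR (%)."""

    c0: float
    c1: float
    c2: float
    amp_max: float

    def target_from_amp(self, amp: np.ndarray | float) -> np.ndarray | float:
        a = np.asarray(amp, dtype=float)
        return self.c0 + self.c1 * np.log1p((a / self.c2) ** 2)

    def amp_from_target(self, target: np.ndarray | float) -> np.ndarray | float:
        """Invert the map; targets are clipped into the calibrated range."""
        y = np.clip(np.asarray(target, dtype=float), self.target_min, self.target_max)
        return self.c2 * np.sqrt(np.expm1((y - self.c0) / self.c1))

    @property
    def target_min(self) -> float:
        return float(self.target_from_amp(0.0))

    @property
    def target_max(self) -> float:
        return float(self.target_from_amp(self.amp_max))


_CALIBRATION_CACHE: dict = {}
_CALIBRATION_SEED = 987_654_321  # fixed: the lookup is a property of params, not of a cohort


def calibrate_burst_mapping(
    params: EEGParams,
    amps: np.ndarray | None = None,
    n_trials_per_amp: int = 48,
    spectral_kwargs: dict | None = None,
) -> BurstCalibration:
    """Run the calibration sweep through the real extraction path.

    For each candidate amplitude, a block of constant-amplitude trials is
    generated and the mean pipeline-extracted PMBR recorded (each amplitude
    is its own normalization block, matching how cohorts are generated: all
    trials of a block share one programmed PMBR).  Results are cached.
    """
    from scipy.optimize import curve_fit

    from ..spectral import subject_pmbr

    amps = np.linspace(0.0, 16.0, 17) if amps is None else np.asarray(amps, float)
    key = (params, tuple(np.round(amps, 9)), n_trials_per_amp,
           tuple(sorted((spectral_kwargs or {}).items())))
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]

    rng = np.random.default_rng(_CALIBRATION_SEED)
    means = np.empty(len(amps))
    for i, a in enumerate(amps):
        epochs = generate_trial_epochs(np.full(n_trials_per_amp, a), params, rng)
        table = subject_pmbr(
            epochs,
            params.sfreq,
            blocks=np.ones(n_trials_per_amp, dtype=int),
            offset_index=params.offset_index,
            **(spectral_kwargs or {}),
        )
        means[i] = table["pmbr_pct"].mean()

    def model(a, c0, c1, c2):
        return c0 + c1 * np.log1p((a / c2) ** 2)

    p0 = (means[0], max(np.ptp(means) / 3.0, 1.0), max(amps.max() / 3.0, 1.0))
    popt, _ = curve_fit(
        model, amps, means, p0=p0,
        bounds=([-np.inf, 1e-6, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20000,
    )
    cal = BurstCalibration(c0=float(popt[0]), c1=float(popt[1]), c2=float(popt[2]),
                           amp_max=float(amps.max()))
    _CALIBRATION_CACHE[key] = cal
    return cal


def generate_trial_eeg(
    pmbr_target: float,
    trial_duration: float = 6.0,
    offset_time: float = 3.0,
    sfreq: float = 256.0,
    snr: float = 2.0,
    rng: np.random.Generator | None = None,
    params: EEGParams | None = None,
) -> np.ndarray:
    """One synthetic trial epoch whose extracted PMBR is ``pmbr_target`` (%)
    in expectation (via the calibrated burst mapping)."""
    rng = np.random.default_rng() if rng is None else rng
    if params is None:
        params = EEGParams(
            sfreq=sfreq, epoch_duration=trial_duration, offset_time=offset_time
        ).with_snr(snr)
    cal = calibrate_burst_mapping(params)
    amp = float(cal.amp_from_target(pmbr_target))
    return generate_trial_epochs(np.array([amp]), params, rng)[0]
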