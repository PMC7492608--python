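"""Trial-by-trial signed directional error series.

The error on trial t is e_t = mu_t + x_t: a systematic bias mu_t decaying
exponentially from an initial to a plateau value, plus an AR(1) fluctuation
x_t whose marginal SD follows its own exponential decay schedule (early
exploration is noisier than the learned plateau) and whose lag-1 coefficient
captures trial-to-trial error persistence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ErrorCurve", "generate_error_series"]


@dataclass(frozen=True)
class ErrorCurve:
    """Per-group error-curve parameters (degrees / trials)."""

    initial_bias: float
    plateau_bias: float
    initial_sd: float
    plateau_sd: float
    decay_constant: float  # trials
    ar1_rho: float

    def __post_init__(self) -> None:
        vals = [self.initial_bias, self.plateau_bias, self.initial_sd,
                self.plateau_sd, self.decay_constant, self.ar1_rho]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("error-curve parameters must be finite")
        if self.initial_sd < 0 or self.plateau_sd < 0:
            raise ValueError("SDs must be nonnegative")
        if self.decay_constant <= 0:
            raise ValueError("decay constant must be positive")
        if not -1.0 <= self.ar1_rho <= 1.0:
            raise ValueError("AR(1) coefficient must lie in [-1, 1]")

    def bias_schedule(self, n_trials: int) -> np.ndarray:
        t = np.arange(n_trials)
        return self.plateau_bias + (self.initial_bias - self.plateau_bias) * np.exp(
            -t / self.decay_constant
        )

    def sd_schedule(self, n_trials: int) -> np.ndarray:
        t = np.arange(n_trials)
        return self.plateau_sd + (self.initial_sd - self.plateau_sd) * np.exp(
            -t / self.decay_constant
        )


def generate_error_series(
    params: ErrorCurve, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Signed directional errors (deg) for one subject's session.

    The AR(1) innovation SD is scheduled so the marginal SD of x_t follows
    the configured decay: innov_t = sqrt(sd_t^2 - rho^2 sd_{t-1}^2), clipped
    at zero when the schedule decays faster than the AR recursion allows.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    mu = params.bias_schedule(n_trials)
    sd = params.sd_schedule(n_trials)
    rho = params.ar1_rho
    x = np.empty(n_trials)
    x[0] = rng.normal(0.0, sd[0])
    innov_var = np.clip(sd[1:] ** 2 - rho**2 * sd[:-1] ** 2, 0.0, None)
    eps = rng.normal(0.0, 1.0, n_trials - 1) * np.sqrt(innov_var)
    for i in range(1, n_trials):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return mu + x
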