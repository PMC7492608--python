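"""Subject-level coupling between block PMBR and block errors.

Each subject carries one true correlation r.  Their 12 block PMBR values are
programmed as

    PMBR_b = offset + scale * (r * z(E_b) + sqrt(1 - r^2) * eta_b),

where z() standardizes the block mean-absolute-error vector and eta is unit
Gaussian, so the expected Pearson correlation of the programmed values with
the block errors equals r (up to small-sample bias) and their SD equals
``scale`` (percent-change units).  True correlations are drawn from
Gaussians truncated at zero: the two learner groups are strictly
sign-separated.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

__all__ = ["program_block_pmbr", "draw_true_correlations"]


def program_block_pmbr(
    true_corr: float,
    block_errors: np.ndarray,
    pmbr_scale: float,
    rng: np.random.Generator,
    offset: float = 0.0,
) -> np.ndarray:
    """Programmed block PMBR values (% change) for one subject."""
    if not np.isfinite(true_corr) or abs(true_corr) > 1:
        raise ValueError("true correlation must lie in [-1, 1]")
    E = np.asarray(block_errors, dtype=float)
    if E.ndim != 1 or len(E) < 2 or not np.all(np.isfinite(E)):
        raise ValueError("block errors must be a finite 1-D vector")
    sd = E.std()
    if sd == 0:
        raise ValueError("block errors have zero variance")
    z = (E - E.mean()) / sd
    eta = rng.standard_normal(len(E))
    return offset + pmbr_scale * (true_corr * z + np.sqrt(1.0 - true_corr**2) * eta)


def draw_true_correlations(
    mean: float,
    sd: float,
    n: int,
    rng: np.random.Generator,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Subject-level true correlations from a truncated Gaussian.

    The Gaussian is centered on ``mean`` and truncated at zero (and ±1) so
    all draws for a negative-coupling group are negative and vice versa.
    Truncation shifts the realized *true* mean away from zero (e.g. location
    −0.40, SD 0.26 realizes a mean of −0.434); this is deliberate — a
    correlation fitted from 12 blocks is attenuated toward zero by sampling
    bias, and the two effects cancel so that the cohort's *fitted* group
    means land on the programmed values.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if bounds is None:
        bounds = (-1.0, 0.0) if mean < 0 else (0.0, 1.0)
    lo, hi = bounds
    if not lo < mean < hi:
        raise ValueError("mean must lie strictly inside the truncation bounds")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
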