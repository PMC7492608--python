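"""Data-driven grouping of learners by their PMBR dynamics.

Each subject's coupling between cortical beta rebound and behavior is
summarized as the Pearson correlation, over the 12 learning blocks, between
the block-averaged PMBR and the block mean absolute directional error.
Negative correlations (PMBR rises as errors fall) mark "increasers",
consistent with error-based adaptation; positive correlations mark
"decreasers", consistent with reward-based skill learning.

The number of latent groups is selected two independent ways: Gaussian
mixture models of 1-5 components compared by AIC and its small-sample
correction AICc, and fuzzy c-means over 2-10 clusters compared by a
within/between validity index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .fuzzy import select_fcm_clusters

__all__ = [
    "pmbr_error_correlation",
    "gmm_select",
    "assign_groups",
    "group_subjects",
    "trend_fit",
    "control_correlations",
    "ModelSelectionCurve",
    "GroupingResult",
    "CORRELATION_REG_COVAR",
]

# Variance floor for mixture components fit to 12-block Pearson correlations.
# An observed r at n = 12 blocks carries sampling SD of roughly
# (1 - r^2)/sqrt(n - 1) ~ 0.2-0.3, so a fitted component narrower than
# SD 0.1 can only be fitting noise; the floor enters EM as a covariance
# regularizer rather than as post-hoc rejection, so fits stay feasible.
CORRELATION_REG_COVAR = 0.01


@dataclass
class ModelSelectionCurve:
    """Information-criterion curves over candidate component counts."""

    counts: list[int]
    aic: list[float]
    aicc: list[float]
    criterion: str  # which criterion picked selected_count
    selected_count: int
    models: dict[int, GaussianMixture] = field(default_factory=dict, repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_components": self.counts, "aic": self.aic, "aicc": self.aicc})


def pmbr_error_correlation(block_pmbr: np.ndarray, block_error: np.ndarray) -> float:
    """Pearson correlation between block PMBR and block mean |error|."""
    x = np.asarray(block_pmbr, dtype=float)
    y = np.asarray(block_error, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two aligned 1-D series of >= 3 blocks")
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _aicc_from(gm: GaussianMixture, X: np.ndarray) -> float:
    n = len(X)
    k = gm._n_parameters()
    if n - k - 1 <= 0:
        return np.inf
    return float(gm.aic(X)) + 2.0 * k * (k + 1) / (n - k - 1)


def gmm_select(
    data: np.ndarray,
    max_components: int = 5,
    seed: int = 0,
    reg_covar: float = 1e-6,
    n_restarts: int = 10,
    criterion: str = "aicc",
    min_weight_points: float = 2.0,
) -> ModelSelectionCurve:
    """Fit diagonal-covariance GMMs of 1..max_components and select by AICc.

    Each count runs ``n_restarts`` EM restarts from k-means++ initializations
    (tolerance 1e-6); restarts whose smallest component supports fewer than
    ``min_weight_points`` observations are treated as degenerate and
    discarded.  A count with no feasible restart, or with undefined AICc
    (n - k - 1 <= 0), scores +inf.  ``criterion`` may be "aicc" or "aic".
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    n, d = X.shape
    if criterion not in ("aic", "aicc"):
        raise ValueError("criterion must be 'aic' or 'aicc'")
    counts, aics, aiccs, models = [], [], [], {}
    for c in range(1, max_components + 1):
        best = None
        feasible = 0
        # degenerate runs (a vanishing component) are restarted from a fresh
        # initialization, up to a 3x attempt budget
        for r in range(3 * n_restarts):
            if feasible >= n_restarts:
                break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = GaussianMixture(
                    n_components=c,
                    covariance_type="diag",
                    n_init=1,
                    tol=1e-6,
                    max_iter=2000,
                    reg_covar=reg_covar,
                    init_params="k-means++",
                    random_state=int((seed * 1000 + r) % (2**31)),
                ).fit(X)
            if gm.weights_.min() < min_weight_points / n:
                continue  # vanishing component: degenerate restart
            feasible += 1
            if best is None or gm.lower_bound_ > best.lower_bound_:
                best = gm
        counts.append(c)
        if best is None:
            aics.append(np.inf)
            aiccs.append(np.inf)
        else:
            models[c] = best
            aics.append(float(best.aic(X)))
            aiccs.append(_aicc_from(best, X))
    crit = aiccs if criterion == "aicc" else aics
    selected = counts[int(np.argmin(crit))]
    return ModelSelectionCurve(
        counts=counts, aic=aics, aicc=aiccs, criterion=criterion,
        selected_count=selected, models=models,
    )


@dataclass
class GroupingResult:
    correlations: np.ndarray
    gmm_curve: ModelSelectionCurve
    fcm_selected: int
    fcm_validity: dict[int, float]
    labels: np.ndarray  # "increaser" / "decreaser" per subject
    sign_pure: bool
    methods_agree: bool
    fallback_to_sign: bool


def assign_groups(
    correlations: np.ndarray, selection: ModelSelectionCurve
) -> tuple[np.ndarray, bool, bool]:
    """Label subjects from the 2-component mixture posterior.

    The component with the lower mean correlation is the "increaser" group.
    Returns (labels, sign_pure, fell_back_to_sign).  If the posterior labels
    are not sign-pure (each group sharing one correlation sign), labels fall
    back to the correlation sign with a warning.  Raises if the selected
    component count is not 2.
    """
    r = np.asarray(correlations, dtype=float)
    if selection.selected_count != 2 or 2 not in selection.models:
        raise ValueError(
            f"grouping undefined: model selection chose {selection.selected_count} components"
        )
    gm = selection.models[2]
    comp = gm.predict(r[:, None])
    neg_comp = int(np.argmin(gm.means_.ravel()))
    labels = np.where(comp == neg_comp, "increaser", "decreaser")
    sign_ok = bool(
        np.all(r[labels == "increaser"] < 0) and np.all(r[labels == "decreaser"] > 0)
    )
    if not sign_ok:
        warnings.warn("mixture labels not sign-pure; falling back to correlation sign")
        labels = np.where(r < 0, "increaser", "decreaser")
        return labels, False, True
    return labels, True, False


def group_subjects(correlations: np.ndarray, seed: int = 0) -> GroupingResult:
    """Full grouping of a cohort's PMBR-error correlations.

    Runs GMM selection (AICc, with the measurement-noise covariance floor)
    and FCM validity selection, labels subjects from the mixture posterior,
    and records whether the two methods agree on the grouping.
    """
    r = np.asarray(correlations, dtype=float)
    sel = gmm_select(r, max_components=5, seed=seed, reg_covar=CORRELATION_REG_COVAR)
    fcm_c, fcm_curve, fcm_fits = select_fcm_clusters(r, c_range=(2, 10), seed=seed)
    if sel.selected_count == 2:
        labels, pure, fell_back = assign_groups(r, sel)
    else:
        warnings.warn(
            f"GMM selected {sel.selected_count} components; labeling by correlation sign"
        )
        labels = np.where(r < 0, "increaser", "decreaser")
        pure, fell_back = True, True
    agree = False
    if fcm_c == 2:
        fcm_labels = fcm_fits[2].labels
        neg_cluster = int(np.argmin(fcm_fits[2].centers.ravel()))
        fcm_named = np.where(fcm_labels == neg_cluster, "increaser", "decreaser")
        agree = bool(np.all(fcm_named == labels))
    return GroupingResult(
        correlations=r,
        gmm_curve=sel,
        fcm_selected=fcm_c,
        fcm_validity=fcm_curve,
        labels=labels,
        sign_pure=pure,
        methods_agree=agree,
        fallback_to_sign=fell_back,
    )


def trend_fit(block_values: np.ndarray) -> dict:
    """OLS of block means on block index, with the F test against the
    intercept-only model.  Returns slope, intercept, F, p, and R^2."""
    import statsmodels.api as sm

    y = np.asarray(block_values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("block values must be finite")
    x = np.arange(1, len(y) + 1, dtype=float)
    if y.std() == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "fvalue": 0.0,
                "pvalue": np.nan, "r2": 0.0}
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "fvalue": float(res.fvalue),
        "pvalue": float(res.f_pvalue),
        "r2": float(res.rsquared),
    }


def control_correlations(
    block_series: dict[str, pd.DataFrame], pmbr_key: str = "pmbr"
) -> pd.DataFrame:
    """Within-subject correlations between block PMBR and each control series.

    ``block_series`` maps series names to (subject x block) DataFrames; the
    PMBR frame is identified by ``pmbr_key``.  Returns one row per subject
    and control pair.  Subjects with missing blocks in a pair are skipped.
    """
    pmbr = block_series[pmbr_key]
    rows = []
    for name, frame in block_series.items():
        if name == pmbr_key:
            continue
        for subj in pmbr.index:
            if subj not in frame.index:
                continue
            x = pmbr.loc[subj].to_numpy(dtype=float)
            y = frame.loc[subj].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            rows.append(
                {"subject": subj, "pair": f"{pmbr_key}-vs-{name}",
                 "r": pmbr_error_correlation(x[ok], y[ok])}
            )
    return pd.DataFrame(rows)


def compare_groups(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Two-sample Welch t-test between group value distributions."""
    t, p = stats.ttest_ind(values_a, values_b, equal_var=False)
    return {"t": float(t), "p": float(p)}
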