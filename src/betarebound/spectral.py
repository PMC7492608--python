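"""Time-frequency analysis and post-movement beta rebound (PMBR) extraction.

The PMBR is a transient increase in beta-band (13-30 Hz) power over
sensorimotor cortex shortly after a movement ends.  Because the task is
self-paced, there is no motion-free baseline: power is expressed as percent
change relative to the block average, computed per frequency as

    value = 100 * (ln P / <ln P>_block - 1),

where ``<ln P>_block`` averages the log power over all edge-valid samples of
every trial in the block.  Note this normalization is unit-dependent (a
global rescaling of the raw signal shifts ``ln P`` additively), so traces are
kept in physical microvolts throughout.

The per-trial PMBR is the mean normalized beta power over a 200-ms window
centered on the peak of the band-averaged series within the 2-s window after
movement offset; movement offset is proxied by the cue-ball movement onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "bandpass",
    "morlet_power",
    "block_normalize",
    "band_average",
    "extract_pmbr",
    "baseline_beta",
    "block_average",
    "subject_pmbr",
    "TFRMap",
]

DEFAULT_FREQS = np.arange(5.0, 36.0)  # 1 Hz steps, 5-35 Hz
BETA_BAND = (13.0, 30.0)


def bandpass(trace: np.ndarray, sfreq: float, low: float = 5.0, high: float = 35.0) -> np.ndarray:
    """Zero-phase FIR band-pass; accepts 1-D traces or (n_trials, n_times)."""
    import mne

    if not 0 < low < high < sfreq / 2:
        raise ValueError(f"band ({low}, {high}) Hz must lie inside (0, Nyquist)")
    x = np.asarray(trace, dtype=np.float64)
    return mne.filter.filter_data(
        x, sfreq, low, high, method="fir", phase="zero", verbose="error"
    )


@dataclass
class TFRMap:
    """Time-frequency representation of a set of trial epochs.

    values : (n_trials, n_freqs, n_times) raw power or normalized % change
    valid  : (n_freqs, n_times) mask, False within half a wavelet of an edge
    times  : seconds, relative to movement offset
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    normalized: bool = False


def _wavelet_halves(sfreq: float, freqs: np.ndarray, n_cycles: float) -> np.ndarray:
    """Half-support (samples) of each Morlet wavelet, for edge flagging."""
    import mne

    ws = mne.time_frequency.morlet(sfreq, freqs, n_cycles=n_cycles)
    return np.array([(len(w) - 1) // 2 for w in ws])


def morlet_power(
    epochs: np.ndarray,
    sfreq: float,
    times: np.ndarray,
    freqs: np.ndarray | None = None,
    n_cycles: float = 7.0,
) -> TFRMap:
    """Squared-magnitude complex Morlet decomposition of trial epochs.

    ``epochs`` is (n_trials, n_times) in µV.  Samples within half a wavelet
    of either epoch edge are flagged invalid per frequency.
    """
    from mne.time_frequency import tfr_array_morlet

    epochs = np.atleast_2d(np.asarray(epochs, dtype=np.float64))
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    n = epochs.shape[1]
    halves = _wavelet_halves(sfreq, freqs, n_cycles)
    if np.any(2 * halves + 1 > n):
        raise ValueError("epoch shorter than the widest wavelet support")
    power = tfr_array_morlet(
        epochs[:, None, :], sfreq, freqs, n_cycles=n_cycles,
        output="power", zero_mean=True, verbose="error",
    )[:, 0]
    valid = np.zeros((len(freqs), n), dtype=bool)
    for fi, h in enumerate(halves):
        valid[fi, h : n - h] = True
    return TFRMap(values=power, freqs=freqs, times=np.asarray(times, float), valid=valid)


def block_normalize(tfr: TFRMap, blocks: np.ndarray, mode: str = "log-then-mean") -> TFRMap:
    """Percent change from the block average, per frequency row.

    ``blocks`` assigns each trial to a block; the block average runs over the
    edge-valid samples of all the block's trials.

    mode="log-then-mean" (default): value = 100*(ln P / <ln P> - 1), the
    literal order of operations (log transform, then normalize by the block
    average of the logs).  mode="mean-then-log" is the documented alternative:
    value = 100*ln(P / <P>), the log ratio to the block-average raw power.
    """
    P = tfr.values
    blocks = np.asarray(blocks)
    if blocks.shape[0] != P.shape[0]:
        raise ValueError("one block index per trial required")
    if np.any(P[:, tfr.valid] <= 0):
        raise ValueError("nonpositive power: upstream numerical fault")
    out = np.empty_like(P)
    for b in np.unique(blocks):
        tm = blocks == b
        if mode == "log-then-mean":
            L = np.log(P[tm])
            for fi in range(len(tfr.freqs)):
                mu = L[:, fi, tfr.valid[fi]].mean()
                if abs(mu) < 1e-12:
                    raise ValueError("degenerate block-mean log power (check signal units)")
                out[tm, fi] = 100.0 * (L[:, fi] / mu - 1.0)
        elif mode == "mean-then-log":
            for fi in range(len(tfr.freqs)):
                mu = P[tm][:, fi, tfr.valid[fi]].mean()
                out[tm, fi] = 100.0 * np.log(P[tm][:, fi] / mu)
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
    return TFRMap(values=out, freqs=tfr.freqs, times=tfr.times, valid=tfr.valid, normalized=True)


def band_average(tfr: TFRMap, band: tuple[float, float] = BETA_BAND) -> tuple[np.ndarray, np.ndarray]:
    """Average a TFRMap over a frequency band.

    Returns (series (n_trials, n_times), valid (n_times,)); a time sample is
    valid only if valid at every frequency in the band.
    """
    sel = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    if not np.any(sel):
        raise ValueError(f"no frequencies inside band {band}")
    return tfr.values[:, sel].mean(axis=1), tfr.valid[sel].all(axis=0)


def extract_pmbr(
    band_series: np.ndarray,
    times: np.ndarray,
    valid: np.ndarray,
    search: tuple[float, float] = (0.0, 2.0),
    window: float = 0.2,
) -> pd.DataFrame:
    """Per-trial PMBR: peak of the band series in the search window, averaged
    over a ``window``-s window centered on the peak.

    ``times`` are relative to movement offset.  Ties break to the earliest
    sample.  The averaging window is truncated at the search-window edges
    (flagged in the ``truncated`` column).  A trial with no valid samples in
    the search window is marked unusable.
    """
    band_series = np.atleast_2d(band_series)
    in_search = (times >= search[0]) & (times <= search[1])
    usable_mask = in_search & valid
    rows = []
    for i, series in enumerate(band_series):
        if not usable_mask.any():
            rows.append({"trial": i + 1, "peak_time_s": np.nan, "pmbr_pct": np.nan,
                         "usable": False, "truncated": False})
            continue
        idx = np.flatnonzero(usable_mask)
        pk = idx[np.argmax(series[idx])]
        t_pk = times[pk]
        half = window / 2.0
        w = usable_mask & (times >= t_pk - half) & (times <= t_pk + half)
        truncated = (t_pk - half < times[idx[0]]) or (t_pk + half > times[idx[-1]])
        rows.append(
            {
                "trial": i + 1,
                "peak_time_s": float(t_pk - search[0]),
                "pmbr_pct": float(series[w].mean()),
                "usable": True,
                "truncated": bool(truncated),
            }
        )
    return pd.DataFrame(rows)


def baseline_beta(
    band_series: np.ndarray,
    times: np.ndarray,
    valid: np.ndarray,
    window: tuple[float, float] = (-0.6, -0.1),
) -> np.ndarray:
    """Mean band power in a pre-onset window (default 500 ms ending 100 ms
    before movement onset); NaN where the window is not covered by valid
    samples."""
    band_series = np.atleast_2d(band_series)
    w = (times >= window[0]) & (times <= window[1]) & valid
    if not w.any():
        return np.full(band_series.shape[0], np.nan)
    return band_series[:, w].mean(axis=1)


def block_average(
    values: np.ndarray, blocks: np.ndarray, usable: np.ndarray | None = None
) -> pd.DataFrame:
    """Arithmetic block means over usable trials; errors on an empty block."""
    values = np.asarray(values, dtype=float)
    blocks = np.asarray(blocks)
    usable = np.ones(len(values), bool) if usable is None else np.asarray(usable, bool)
    usable = usable & np.isfinite(values)
    rows = []
    for b in np.unique(blocks):
        tm = (blocks == b) & usable
        n_excl = int(((blocks == b) & ~usable).sum())
        if not tm.any():
            raise ValueError(f"block {b} has no usable trials")
        rows.append({"block": int(b), "mean": float(values[tm].mean()),
                     "n_trials": int(tm.sum()), "n_excluded": n_excl})
    return pd.DataFrame(rows)


def subject_pmbr(
    epochs: np.ndarray,
    sfreq: float,
    blocks: np.ndarray,
    offset_index: int,
    band: tuple[float, float] = BETA_BAND,
    freqs: np.ndarray | None = None,
    n_cycles: float = 7.0,
    crop: tuple[float, float] = (-1.2, 2.6),
    search: tuple[float, float] = (0.0, 2.0),
    window: float = 0.2,
    baseline_window: tuple[float, float] = (-0.6, -0.1),
    filter_band: tuple[float, float] = (5.0, 35.0),
    norm_mode: str = "log-then-mean",
) -> pd.DataFrame:
    """Full per-trial PMBR path for one subject's trial epochs.

    ``epochs`` is (n_trials, n_times) µV with movement offset at sample
    ``offset_index``.  Epochs are band-pass filtered, cropped to ``crop``
    seconds around the offset, Morlet-decomposed over the analysis band,
    block-normalized, band-averaged, and peak-extracted.  Returns a table
    with trial, block, peak_time_s, pmbr_pct, baseline_pct, usable.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=np.float64))
    if freqs is None:
        freqs = np.arange(band[0], band[1] + 1.0)
    filtered = bandpass(epochs, sfreq, *filter_band)
    times_full = (np.arange(epochs.shape[1]) - offset_index) / sfreq
    sel = (times_full >= crop[0]) & (times_full <= crop[1])
    tfr = morlet_power(filtered[:, sel], sfreq, times_full[sel], freqs=freqs, n_cycles=n_cycles)
    tfr = block_normalize(tfr, blocks, mode=norm_mode)
    series, valid = band_average(tfr, band)
    out = extract_pmbr(series, tfr.times, valid, search=search, window=window)
    out["baseline_pct"] = baseline_beta(series, tfr.times, valid, window=baseline_window)
    out["block"] = np.asarray(blocks)
    return out[["trial", "block", "peak_time_s", "pmbr_pct", "baseline_pct", "usable", "truncated"]]
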