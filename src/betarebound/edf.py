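"""Minimal single-purpose EDF (European Data Format) writer.

Writes one-channel continuous EEG as a standard 16-bit EDF file that any EDF
reader (``mne.io.read_raw_edf`` is used throughout this package) can open.
Only the subset of the format needed here is implemented: one data record per
second, one signal, physical units in microvolts.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf"]


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sfreq: float,
    ch_name: str = "C3",
    phys_unit: str = "uV",
) -> Path:
    """Write a 1-D microvolt trace to ``path`` as EDF.

    The trace is split into 1-second data records; its length must be a whole
    number of seconds.  Values are linearly quantized to int16 over the
    symmetric physical range covering the data.
    """
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if data.ndim != 1:
        raise ValueError("write_edf expects a single-channel 1-D trace")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite samples cannot be written to EDF")
    spr = int(round(sfreq))
    if spr <= 0 or abs(sfreq - spr) > 1e-9:
        raise ValueError("sampling rate must be a positive integer for 1-s records")
    if len(data) % spr != 0:
        raise ValueError("trace length must be a whole number of 1-s records")
    n_records = len(data) // spr

    phys_max = float(max(np.abs(data).max(), 1.0)) * 1.05
    # scale with exactly the (2-decimal) values written to the header, so the
    # reader's inverse mapping matches the writer's quantization
    phys_max = float(f"{phys_max + 0.005:.2f}")
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min).astype("<i2")

    t0 = datetime.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate 01-JAN-2000 X X X", 80),
            _field(t0.strftime("%d.%m.%y"), 8),
            _field(t0.strftime("%H.%M.%S"), 8),
            _field(256 + 256, 8),  # header bytes: fixed + one signal block
            _field("", 44),
            _field(n_records, 8),
            _field(1, 8),  # record duration, seconds
            _field(1, 4),  # number of signals
        ]
    )
    sig = b"".join(
        [
            _field(f"EEG {ch_name}", 16),
            _field("", 80),
            _field(phys_unit, 8),
            _field(f"{phys_min:.2f}"[:8], 8),
            _field(f"{phys_max:.2f}"[:8], 8),
            _field(dig_min, 8),
            _field(dig_max, 8),
            _field("", 80),
            _field(spr, 8),
            _field("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        fh.write(digital.tobytes())
    return path


def read_edf(path: str | Path) -> tuple[np.ndarray, float, str]:
    """Read a single-channel EDF through MNE; returns (µV trace, sfreq, label)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[0] * 1e6  # MNE loads EDF in volts
    return data, float(raw.info["sfreq"]), raw.ch_names[0]
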