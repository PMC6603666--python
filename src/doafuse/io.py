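"""Reading and writing EEG records and per-minute index series.

All amplitudes are handled in microvolts (µV) internally.  Two on-disk
formats are supported for raw signals: EDF (single-channel, continuous)
and a two-column CSV ``time_s, amplitude_uV``.  Per-minute index series
(0–100 scale, BIS-like) are stored as CSV ``minute, value`` with an
optional ``state`` column.

Minutes are 0-based and half-open: minute ``m`` covers ``[m, m+1)``
seconds × 60 from the start of the record.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EegRecord",
    "IndexSeries",
    "read_record",
    "write_record",
    "read_index_series",
    "write_index_series",
]


@dataclass
class EegRecord:
    """A single-channel EEG signal.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in µV.
    fs : float
        Sampling rate in Hz, > 0.
    channel_label : str
        Channel name (frontal montage by convention).
    start_time : datetime, optional
        Acquisition start; purely informational.
    annotations : list of (float, str)
        ``(time_s, label)`` event markers.
    """

    samples: np.ndarray
    fs: float
    channel_label: str = "EEG Fpz-At1"
    start_time: datetime | None = None
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def duration_minutes(self) -> int:
        """Whole minutes contained in the record."""
        return int(self.duration_s // 60)

    def copy(self, samples: np.ndarray | None = None, fs: float | None = None) -> "EegRecord":
        return EegRecord(
            samples=self.samples.copy() if samples is None else np.asarray(samples, float),
            fs=self.fs if fs is None else fs,
            channel_label=self.channel_label,
            start_time=self.start_time,
            annotations=list(self.annotations),
        )


@dataclass
class IndexSeries:
    """Per-minute 0–100 index values (e.g. a BIS-like reference)."""

    values: np.ndarray
    minute_offsets: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.minute_offsets = np.asarray(self.minute_offsets, dtype=int)
        if self.values.shape != self.minute_offsets.shape:
            raise ValueError("values and minute_offsets must have equal length")
        if self.minute_offsets.size and np.any(np.diff(self.minute_offsets) <= 0):
            raise ValueError("minute offsets must be strictly increasing")
        finite = np.isfinite(self.values)
        if np.any((self.values[finite] < 0) | (self.values[finite] > 100)):
            bad = self.values[finite][(self.values[finite] < 0) | (self.values[finite] > 100)][0]
            raise ValueError(f"index values must lie in [0, 100]; found {bad}")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# EDF: a minimal standard-conformant single-channel writer plus an mne-backed
# reader.  EDF stores 16-bit integers with a per-signal physical/digital
# calibration, so a write→read round trip is exact only to the quantization
# step of the declared physical range.
# ---------------------------------------------------------------------------

_EDF_DIGITAL_MIN = -32768
_EDF_DIGITAL_MAX = 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(record: EegRecord, path: Path) -> None:
    x = record.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("record contains non-finite samples; EDF requires finite data")
    fs = record.fs
    # one data record per second when fs is integral, else a single big record
    if abs(fs - round(fs)) < 1e-9:
        spr = int(round(fs))
        record_dur = 1.0
    else:
        spr = x.size
        record_dur = x.size / fs
    n_records = int(np.ceil(x.size / spr))
    pad = n_records * spr - x.size
    if pad:
        x = np.concatenate([x, np.full(pad, x[-1])])

    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-6:  # flat signal: widen so the gain is nonzero
        lo, hi = lo - 1.0, hi + 1.0
    gain = (hi - lo) / (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN)
    digital = np.round((x - lo) / gain + _EDF_DIGITAL_MIN).astype("<i2")

    start = record.start_time or datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),  # patient id (anonymous)
            _edf_field("Startdate X X X X", 80),
            _edf_field(start.strftime("%d.%m.%y"), 8),
            _edf_field(start.strftime("%H.%M.%S"), 8),
            _edf_field(str(256 + 256), 8),  # header bytes: 256 + 256*nsignals
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field(f"{record_dur:g}", 8),
            _edf_field("1", 4),
        ]
    )
    sig_header = b"".join(
        [
            _edf_field(record.channel_label, 16),
            _edf_field("AgAgCl electrode", 80),
            _edf_field("uV", 8),
            _edf_field(f"{lo:.6g}", 8),
            _edf_field(f"{hi:.6g}", 8),
            _edf_field(str(_EDF_DIGITAL_MIN), 8),
            _edf_field(str(_EDF_DIGITAL_MAX), 8),
            _edf_field("", 80),  # prefiltering
            _edf_field(str(spr), 8),
            _edf_field("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.tobytes())


def _read_edf(path: Path) -> EegRecord:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[0] * 1e6  # mne loads volts; convert to µV
    meas = raw.info.get("meas_date")
    start = None
    if meas is not None:
        start = datetime(meas.year, meas.month, meas.day, meas.hour, meas.minute, meas.second)
    return EegRecord(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_label=raw.ch_names[0],
        start_time=start,
    )


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _read_csv_record(path: Path) -> EegRecord:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("CSV record needs columns (time_s, amplitude_uV)")
    t = df.iloc[:, 0].to_numpy(float)
    x = df.iloc[:, 1].to_numpy(float)
    if t.size < 2:
        raise ValueError("CSV record must contain at least two samples")
    dt = np.diff(t)
    dt0 = np.median(dt)
    rel = np.abs(dt - dt0) / dt0
    if np.any(rel > 1e-6):
        i = int(np.argmax(rel > 1e-6))
        raise ValueError(
            f"non-uniform timebase: interval between rows {i} and {i + 1} is "
            f"{dt[i]:.9g} s, expected {dt0:.9g} s"
        )
    return EegRecord(samples=x, fs=1.0 / dt0)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer format from extension {suffix!r}; pass format=")


def read_record(path: str | Path, format: str | None = None) -> EegRecord:
    """Read a single-channel EEG record from EDF or CSV.

    For CSV, the sampling rate is inferred from the time column, which must
    be uniform to within a 1e-6 relative tolerance.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv_record(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'csv'")


def write_record(record: EegRecord, path: str | Path, format: str | None = None) -> Path:
    """Write a record to EDF or CSV.  CSV round-trips at full float precision."""
    path = Path(path)
    if not np.all(np.isfinite(record.samples)):
        raise ValueError("record contains NaN/inf samples; refusing to write")
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(record, path)
    elif fmt == "csv":
        t = np.arange(record.samples.size) / record.fs
        pd.DataFrame({"time_s": t, "amplitude_uV": record.samples}).to_csv(
            path, index=False, float_format="%.17g"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'csv'")
    return path


def read_index_series(path: str | Path) -> IndexSeries:
    """Read a per-minute index CSV with columns ``minute, value`` (header row).

    Values must lie in [0, 100]; empty cells are kept as NaN (missing).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("index CSV needs columns (minute, value)")
    minutes = df.iloc[:, 0].to_numpy()
    values = df.iloc[:, 1].to_numpy(float)
    if not np.allclose(minutes, np.round(minutes)):
        raise ValueError("minute column must be integral")
    return IndexSeries(values=values, minute_offsets=np.round(minutes).astype(int))


def write_index_series(
    series: IndexSeries, path: str | Path, states: list[str] | None = None
) -> Path:
    path = Path(path)
    data = {"minute": series.minute_offsets, "value": series.values}
    if states is not None:
        data["state"] = states
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path
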