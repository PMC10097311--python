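"""Core data containers and file I/O.

The package works with two kinds of raw material: sampled single-lead ECG
(:class:`ECGRecord`) and beat-to-beat marker tables (:class:`BeatSeries`).
Beat-series CSV is the canonical interchange format between pipeline stages;
raw ECG input is optional, since markers may be supplied directly.

Apnea annotations are half-open intervals ``[onset_s, offset_s)`` in seconds
from recording start.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ECGRecord",
    "BeatSeries",
    "RunConfig",
    "FormatError",
    "AnnotationError",
    "read_recording",
    "write_recording",
    "read_beat_series",
    "write_beat_series",
    "read_intervals",
    "write_intervals",
]

#: Marker columns understood by the beat-series CSV format, in canonical order.
MARKER_COLUMNS = ("RR", "Ra", "Sa", "RSd", "US", "DS", "QRSpca")


class FormatError(ValueError):
    """Malformed input file (bad header, non-monotone time axis, bad label)."""


class AnnotationError(ValueError):
    """Invalid apnea interval annotations (overlap, inverted, out of range)."""


def _validate_intervals(intervals: Sequence[tuple[float, float]],
                        duration: float | None = None) -> list[tuple[float, float]]:
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    for onset, offset in ivs:
        if not onset < offset:
            raise AnnotationError(f"interval has onset {onset} >= offset {offset}")
        if duration is not None and (onset < 0 or offset > duration + 1e-9):
            raise AnnotationError(
                f"interval [{onset}, {offset}) outside recording [0, {duration})")
    for (a0, b0), (a1, _) in zip(ivs, ivs[1:]):
        if a1 < b0:
            raise AnnotationError(f"intervals [{a0},{b0}) and starting {a1} overlap")
    return ivs


@dataclass
class ECGRecord:
    """Sampled single-lead ECG.

    Parameters
    ----------
    signal : ndarray
        Voltage samples in mV (arbitrary gain allowed).
    fs : float
        Sampling rate in Hz.
    annotations : list of (onset_s, offset_s)
        Optional apnea intervals, half-open, non-overlapping, seconds from
        recording start.
    """

    signal: np.ndarray
    fs: float
    annotations: list[tuple[float, float]] = field(default_factory=list)
    subject_id: str = ""
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.signal.ndim != 1 or self.signal.size < 2:
            raise ValueError("signal must be a 1-D array with at least 2 samples")
        self.annotations = _validate_intervals(self.annotations, self.duration)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.signal.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signal.size) / self.fs


@dataclass
class BeatSeries:
    """Per-beat timestamps with marker columns and an optional apnea label.

    ``table`` has a strictly increasing ``t_s`` column plus any subset of the
    canonical marker columns (RR, Ra, Sa, RSd, US, DS, QRSpca) and an optional
    binary ``apnea`` column. Missing markers are absent, never imputed.
    """

    table: pd.DataFrame
    subject_id: str = ""
    recording_id: str = ""

    def __post_init__(self) -> None:
        df = self.table
        if "t_s" not in df.columns:
            raise FormatError("beat series requires a 't_s' column")
        t = df["t_s"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)):
            raise FormatError("non-finite beat times")
        if np.any(np.diff(t) <= 0):
            raise FormatError("beat times must be strictly increasing")
        if "apnea" in df.columns:
            ap = df["apnea"].to_numpy()
            if not np.isin(ap, (0, 1)).all():
                raise FormatError("apnea labels must be 0 or 1")
            self.table = df.assign(apnea=ap.astype(int))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def t_s(self) -> np.ndarray:
        return self.table["t_s"].to_numpy(dtype=float)

    @property
    def markers(self) -> list[str]:
        """Marker columns present, in canonical order."""
        return [c for c in MARKER_COLUMNS if c in self.table.columns]

    @property
    def apnea(self) -> np.ndarray | None:
        if "apnea" not in self.table.columns:
            return None
        return self.table["apnea"].to_numpy(dtype=int)

    def marker(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)


@dataclass
class RunConfig:
    """Pipeline configuration shared across stages.

    Attributes
    ----------
    order : int
        Markov order L of the network, in beats.
    poly_order : int
        Detrending polynomial order.
    smooth_window : int
        Posterior moving-average window in beats; even values are widened to
        the next odd length so the filter is symmetric (40 -> 41).
    epoch_len_s : float
        Epoch length in seconds for RMS-based classification.
    delta : float
        Decision threshold on the per-epoch RMS of the smoothed posterior.
    markers : tuple of str
        Input marker series fed to the network.
    seed : int
        Root seed; all randomness in a run flows from one generator seeded
        with this value.
    """

    order: int = 5
    poly_order: int = 20
    smooth_window: int = 40
    epoch_len_s: float = 15.0
    delta: float = 0.2
    markers: tuple[str, ...] = ("RR", "DS")
    seed: int = 0
    alpha: float = 0.05
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if not self.epoch_len_s > 0:
            raise ValueError("epoch_len_s must be positive")
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if isinstance(self.markers, (list, str)):
            self.markers = tuple([self.markers] if isinstance(self.markers, str)
                                 else self.markers)

    @property
    def smooth_window_odd(self) -> int:
        w = int(self.smooth_window)
        return w if w % 2 == 1 else w + 1

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML (or JSON) mapping of field names to values."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# ECG record I/O (CSV with a time column, plus sidecar interval annotations)
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str = "csv") -> ECGRecord:
    """Read a sampled ECG record.

    CSV format: header ``time_s,ecg``; the sampling rate is inferred from the
    median time step and the time axis must be strictly increasing and
    uniform. A companion ``<stem>.intervals.csv`` file, if present, supplies
    apnea annotations.
    """
    path = Path(path)
    if format != "csv":
        raise ValueError(f"unsupported record format: {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if not {"time_s", "ecg"} <= set(df.columns):
        raise FormatError("record CSV must have columns 'time_s,ecg'")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError("non-monotone time column")
    step = float(np.median(dt))
    if not np.allclose(dt, step, rtol=1e-6, atol=step * 1e-6):
        raise FormatError("time column is not uniformly sampled")
    fs = 1.0 / step
    ann_path = path.with_suffix("").with_suffix(".intervals.csv") \
        if path.suffix else path
    ann_path = path.parent / (path.stem + ".intervals.csv")
    annotations = read_intervals(ann_path) if ann_path.exists() else []
    return ECGRecord(signal=df["ecg"].to_numpy(dtype=float), fs=fs,
                     annotations=annotations)


def write_recording(rec: ECGRecord, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": rec.times, "ecg": rec.signal}).to_csv(
        path, index=False, float_format="%.9g")
    if rec.annotations:
        write_intervals(rec.annotations, path.parent / (path.stem + ".intervals.csv"))


def read_intervals(path: str | Path) -> list[tuple[float, float]]:
    """Read apnea annotations: CSV with header ``onset_s,offset_s``."""
    df = pd.read_csv(path)
    if not {"onset_s", "offset_s"} <= set(df.columns):
        raise FormatError("interval CSV must have columns 'onset_s,offset_s'")
    return _validate_intervals(list(zip(df["onset_s"], df["offset_s"])))


def write_intervals(intervals: Sequence[tuple[float, float]],
                    path: str | Path) -> None:
    pd.DataFrame(intervals, columns=["onset_s", "offset_s"]).to_csv(
        path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Beat-series I/O
# ---------------------------------------------------------------------------

def read_beat_series(path: str | Path) -> BeatSeries:
    """Read a beat-series CSV (``t_s`` + marker subset + optional ``apnea``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "t_s" not in df.columns:
        raise FormatError("beat-series CSV must have a 't_s' column")
    allowed = {"t_s", "apnea", *MARKER_COLUMNS}
    unknown = set(df.columns) - allowed
    if unknown:
        raise FormatError(f"unknown beat-series columns: {sorted(unknown)}")
    return BeatSeries(table=df)


def write_beat_series(bs: BeatSeries, path: str | Path) -> None:
    cols = ["t_s"] + bs.markers + (["apnea"] if bs.apnea is not None else [])
    bs.table[cols].to_csv(path, index=False, float_format="%.12g")

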