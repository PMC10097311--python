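"""Detrending, normalization and per-beat apnea labelling.

Marker amplitudes vary substantially between recordings and drift slowly
within one; only the apnea-coupled fluctuations carry detection signal. Each
marker series is therefore detrended by removing a high-order (default 20)
polynomial trend fitted on beat index, then z-score normalized per
recording. The polynomial is fitted in a Legendre basis on the index
rescaled to [-1, 1]: at order 20 a raw monomial basis is numerically
hopeless, while the orthogonal basis keeps the least-squares problem well
conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import AnnotationError, BeatSeries

__all__ = [
    "DetrendedSeries",
    "detrend_series",
    "normalize_series",
    "label_beats",
    "prepare_markers",
]


@dataclass
class DetrendedSeries:
    """Residual of a polynomial detrend; ``values + trend`` reconstructs input."""

    values: np.ndarray
    trend: np.ndarray


def detrend_series(series: np.ndarray, order: int = 20) -> DetrendedSeries:
    """Remove a least-squares polynomial trend of the given order.

    The fit runs on beat index rescaled to [-1, 1] in a Legendre basis. The
    operation is a linear projection, so it distributes over linear
    combinations of inputs.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if order < 0:
        raise ValueError("order must be >= 0")
    if len(x) <= order + 1:
        raise ValueError(
            f"series of length {len(x)} too short for order-{order} detrend")
    idx = np.arange(len(x), dtype=float)
    fit = np.polynomial.legendre.Legendre.fit(idx, x, deg=order)
    trend = fit(idx)
    return DetrendedSeries(values=x - trend, trend=trend)


def normalize_series(series: np.ndarray) -> DetrendedSeries:
    """Z-score a series; the removed affine part is returned as ``trend``."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot normalize a constant series (SD == 0)")
    mu = x.mean()
    z = (x - mu) / sd
    return DetrendedSeries(values=z, trend=x - z)


def label_beats(beat_times: np.ndarray,
                apnea_intervals) -> np.ndarray:
    """Per-beat binary apnea labels from half-open [onset, offset) intervals."""
    t = np.asarray(beat_times, dtype=float)
    ivs = sorted((float(a), float(b)) for a, b in apnea_intervals)
    for onset, offset in ivs:
        if not onset < offset:
            raise AnnotationError(f"interval onset {onset} >= offset {offset}")
    for (a0, b0), (a1, _) in zip(ivs, ivs[1:]):
        if a1 < b0:
            raise AnnotationError("overlapping apnea intervals")
    labels = np.zeros(len(t), dtype=int)
    for onset, offset in ivs:
        labels[(t >= onset) & (t < offset)] = 1
    return labels


def prepare_markers(bs: BeatSeries, markers, poly_order: int = 20,
                    normalize: bool = True) -> pd.DataFrame:
    """Detrend (and z-score) the requested marker columns of a beat series.

    Returns a DataFrame with one processed column per marker, aligned to the
    beat series. The first RR entry of a recording has no preceding beat; it
    is backfilled with the second value before detrending.
    """
    out = {}
    for m in markers:
        if m not in bs.table.columns:
            raise KeyError(f"marker {m!r} not present in beat series")
        x = bs.marker(m).copy()
        if np.isnan(x[0]) and len(x) > 1:
            x[0] = x[1]
        d = detrend_series(x, order=poly_order)
        v = d.values
        if normalize:
            v = normalize_series(v).values
        out[m] = v
    return pd.DataFrame(out, index=bs.table.index)
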