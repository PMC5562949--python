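"""Preparation of minute-sampled MAP/SctO2 recordings for wavelet analysis.

Bedside recordings of mean arterial pressure (MAP, mmHg) and cerebral tissue
oxygen saturation (SctO2, %) are sampled once per minute and interrupted
whenever the patient is transported.  Before any time-frequency analysis the
signals need three things done to them:

1. spike-like artifacts removed by linear interpolation between neighbours,
2. the recording split into contiguous segments at the transport gaps,
3. slow drifts removed per segment by a second-order polynomial fit.

Spike detection automates what is usually done by eye: a sample is flagged
when the absolute first difference exceeds ``z_thresh`` robust standard
deviations (1.4826 x MAD) of the first differences of the segment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SignalKind",
    "PhysioSeries",
    "Segment",
    "remove_spikes",
    "detrend_poly2",
    "segment_valid",
    "read_physio_csv",
]


class SignalKind(str, enum.Enum):
    MAP = "MAP"
    SCTO2 = "SctO2"


class UnusableRecordingError(ValueError):
    """Raised when a recording contains no usable signal."""


@dataclass(frozen=True)
class PhysioSeries:
    """One uniformly minute-sampled physiological signal with a gap mask.

    Parameters
    ----------
    timestamps:
        Minutes since recording start; strictly increasing with a constant
        step ``dt`` (1 min for bedside monitors).
    values:
        Signal amplitude (mmHg for MAP, % for SctO2).  Samples inside gaps
        may be NaN; samples where ``valid_mask`` is true must be finite.
    valid_mask:
        False inside recording gaps (e.g. patient transportation).
    kind:
        Which physiological signal this is.
    """

    timestamps: np.ndarray
    values: np.ndarray
    valid_mask: np.ndarray
    kind: SignalKind

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if ts.ndim != 1 or ts.size < 2:
            raise ValueError("a PhysioSeries needs at least two samples")
        if vals.shape != ts.shape or mask.shape != ts.shape:
            raise ValueError("timestamps, values and valid_mask must share a shape")
        steps = np.diff(ts)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-8):
            raise ValueError("timestamps must be strictly increasing with constant step")
        if not np.all(np.isfinite(vals[mask])):
            raise ValueError("values must be finite wherever valid_mask is true")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "valid_mask", mask)

    @property
    def dt(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    def __len__(self) -> int:
        return self.timestamps.size

    def with_values(self, values: np.ndarray) -> "PhysioSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class Segment:
    """Half-open index run ``[start, end)`` where both signals are valid."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("segment bounds must satisfy 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start

    def slice(self) -> slice:
        return slice(self.start, self.end)


def _spike_flags(values: np.ndarray, valid: np.ndarray, z_thresh: float) -> np.ndarray:
    """Flag samples adjacent to a robust-z outlying first difference.

    The robust scale is 1.4826 x MAD of the first differences of valid
    samples; when the MAD degenerates to zero (flat signal plus isolated
    spikes) the mean absolute deviation steps in.  Both endpoints of an
    outlying difference are flagged: an interior spike contributes two
    large differences so it and its (harmlessly re-interpolated)
    neighbours are caught, and a spike at either end of the record — which
    contributes only one — is caught as well.
    """
    flags = np.zeros(values.size, dtype=bool)
    idx = np.flatnonzero(valid)
    if idx.size < 3:
        return flags
    dv = np.diff(values[idx])
    med = np.median(dv)
    scale = 1.4826 * np.median(np.abs(dv - med))
    if scale == 0.0:
        scale = 1.2533 * np.mean(np.abs(dv - med))
    if scale == 0.0:
        return flags  # constant signal: nothing to flag
    big = np.abs(dv) > z_thresh * scale
    flags[idx[:-1][big]] = True
    flags[idx[1:][big]] = True
    return flags


def remove_spikes(series: PhysioSeries, z_thresh: float = 5.0) -> PhysioSeries:
    """Replace spike artifacts by linear interpolation between neighbours.

    A sample is a spike when the robust z-score of the first difference of
    valid samples exceeds ``z_thresh``.  Flagged samples are replaced by
    linear interpolation between the nearest non-spike valid neighbours;
    flagged endpoints take the nearest surviving value (constant
    extrapolation).  Idempotent: a second pass finds nothing.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    valid = series.valid_mask
    if valid.sum() < 3:
        raise UnusableRecordingError("need at least 3 valid samples")
    flags = _spike_flags(series.values, valid, z_thresh)
    if not np.any(flags):
        return series
    keep = valid & ~flags
    if keep.sum() == 0:
        raise UnusableRecordingError("every valid sample was flagged as a spike")
    out = series.values.copy()
    t = series.timestamps
    out[flags] = np.interp(t[flags], t[keep], series.values[keep])
    return series.with_values(out)


def detrend_poly2(series: PhysioSeries, degree: int = 2) -> PhysioSeries:
    """Remove slow drifts with an ordinary least-squares polynomial fit.

    Returns the residuals of a degree-``degree`` polynomial in time fitted
    to the valid samples.  Residuals are mean-zero and orthogonal to the
    polynomial basis by construction.  Invalid samples are set to NaN.
    """
    valid = series.valid_mask
    if valid.sum() < degree + 1:
        raise UnusableRecordingError(
            f"need at least {degree + 1} valid samples to fit a degree-{degree} trend"
        )
    t = series.timestamps[valid]
    # center/scale time for conditioning; residuals are unaffected
    t0, tsc = t.mean(), max(np.ptp(t), 1.0)
    coeffs = np.polynomial.polynomial.polyfit(
        (t - t0) / tsc, series.values[valid], deg=degree
    )
    out = np.full(series.values.shape, np.nan)
    out[valid] = series.values[valid] - np.polynomial.polynomial.polyval(
        (t - t0) / tsc, coeffs
    )
    return series.with_values(out)


def segment_valid(
    pair: tuple[PhysioSeries, PhysioSeries], min_len: int = 256
) -> list[Segment]:
    """Maximal runs where both signals are valid, discarding short runs.

    ``min_len`` defaults to four times the largest analysis scale in
    samples (4 x 64 min), so every retained segment supports the full
    scale range outside severe edge effects.
    """
    x, y = pair
    if len(x) != len(y) or not np.array_equal(x.timestamps, y.timestamps):
        raise ValueError("paired series must share timestamps")
    joint = x.valid_mask & y.valid_mask
    edges = np.diff(joint.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if joint[0]:
        starts.insert(0, 0)
    if joint[-1]:
        ends.append(joint.size)
    return [
        Segment(int(s), int(e))
        for s, e in zip(starts, ends)
        if e - s >= max(int(min_len), 1)
    ]


def read_physio_csv(path) -> tuple[PhysioSeries, PhysioSeries]:
    """Read a paired recording from CSV.

    Expected header ``time_min,map_mmhg,scto2_pct``; empty cells denote
    recording gaps.  Returns (MAP, SctO2) sharing timestamps.
    """
    df = pd.read_csv(path)
    required = {"time_min", "map_mmhg", "scto2_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"physiological CSV missing columns: {sorted(missing)}")
    t = df["time_min"].to_numpy(dtype=float)
    series = []
    for col, kind in (("map_mmhg", SignalKind.MAP), ("scto2_pct", SignalKind.SCTO2)):
        v = df[col].to_numpy(dtype=float)
        series.append(
            PhysioSeries(timestamps=t, values=v, valid_mask=np.isfinite(v), kind=kind)
        )
    return series[0], series[1]


def write_physio_csv(path, map_series: PhysioSeries, scto2_series: PhysioSeries) -> None:
    """Inverse of :func:`read_physio_csv`; gaps become empty cells."""
    m = map_series.values.copy()
    m[~map_series.valid_mask] = np.nan
    s = scto2_series.values.copy()
    s[~scto2_series.valid_mask] = np.nan
    pd.DataFrame(
        {"time_min": map_series.timestamps, "map_mmhg": m, "scto2_pct": s}
    ).to_csv(path, index=False)
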