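"""Percent-significant coherence P(s) and the autoregulation index Pmean.

Impaired ("pressure-passive") cerebral autoregulation shows up as
significant *in-phase* coherence between MAP and SctO2: pressure swings
drive oxygenation in the same direction.  The relative phase is binned
into four quadrants of the circle:

- in phase, ``dphi in 0 +/- pi/4`` — pressure-passive pattern;
- antiphase, ``dphi in pi +/- pi/4``;
- two asynchronous quadrature bins, ``+pi/2 +/- pi/4`` and ``-pi/2 +/- pi/4``.

P(s) is the percentage of usable time (inside a valid segment, outside the
cone of influence) at which coherence is significant with the phase in a
given bin.  The scalar autoregulation index is the unweighted mean of the
in-phase P(s) over scales whose Fourier period lies in 8-32 min — the band
where pressure-passive coupling is concentrated (0.0005-0.002 Hz).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Segment
from .significance import SignificanceMap
from .wavelet import WTCField

__all__ = [
    "PhaseBin",
    "ScaleProfile",
    "AutoregIndex",
    "phase_bin",
    "phase_bin_array",
    "percent_significant",
    "autoreg_index",
]

DEFAULT_BAND = (8.0, 32.0)


class PhaseBin(str, enum.Enum):
    IN_PHASE = "in_phase"
    ANTI_PHASE = "anti_phase"
    LEAD_QUAD = "lead_quad"
    LAG_QUAD = "lag_quad"


@dataclass
class ScaleProfile:
    """Per-scale percent significant coherence, split by phase bin.

    ``p`` maps each :class:`PhaseBin` to a vector over ``periods`` (0-100,
    NaN where no usable time exists); ``usable_count`` is the number of
    time points per scale outside the COI and inside valid segments;
    ``sig_count`` the per-bin significant counts.
    """

    periods: np.ndarray
    p: dict[PhaseBin, np.ndarray]
    usable_count: np.ndarray
    sig_count: dict[PhaseBin, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period_min": self.periods,
                "P_inphase": self.p[PhaseBin.IN_PHASE],
                "P_antiphase": self.p[PhaseBin.ANTI_PHASE],
                "P_leadquad": self.p[PhaseBin.LEAD_QUAD],
                "P_lagquad": self.p[PhaseBin.LAG_QUAD],
                "usable_count": self.usable_count,
            }
        )


@dataclass(frozen=True)
class AutoregIndex:
    """Scalar autoregulation-impairment index (percent, 0-100)."""

    pmean: float
    band: tuple[float, float] = DEFAULT_BAND
    phase: PhaseBin = PhaseBin.IN_PHASE
    n_scales_in_band: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pmean <= 100.0:
            raise ValueError("pmean must lie in [0, 100]")


def phase_bin(delta_phi: float) -> PhaseBin:
    """Classify a relative phase (radians, in (-pi, pi]) into its quadrant.

    Bins are lower-inclusive, upper-exclusive: [-pi/4, pi/4) is in-phase,
    [pi/4, 3pi/4) leading quadrature, [3pi/4, pi] plus (-pi, -3pi/4)
    antiphase, [-3pi/4, -pi/4) lagging quadrature.
    """
    if not np.isfinite(delta_phi):
        raise ValueError("phase must be finite")
    if not -np.pi < delta_phi <= np.pi + 1e-12:
        raise ValueError("phase must lie in (-pi, pi]")
    q = np.pi / 4.0
    if -q <= delta_phi < q:
        return PhaseBin.IN_PHASE
    if q <= delta_phi < 3.0 * q:
        return PhaseBin.LEAD_QUAD
    if -3.0 * q <= delta_phi < -q:
        return PhaseBin.LAG_QUAD
    return PhaseBin.ANTI_PHASE


def phase_bin_array(phase: np.ndarray) -> dict[PhaseBin, np.ndarray]:
    """Vectorized phase binning; returns a boolean mask per bin."""
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase array must be finite")
    q = np.pi / 4.0
    masks = {
        PhaseBin.IN_PHASE: (phase >= -q) & (phase < q),
        PhaseBin.LEAD_QUAD: (phase >= q) & (phase < 3 * q),
        PhaseBin.LAG_QUAD: (phase >= -3 * q) & (phase < -q),
    }
    masks[PhaseBin.ANTI_PHASE] = ~(
        masks[PhaseBin.IN_PHASE] | masks[PhaseBin.LEAD_QUAD] | masks[PhaseBin.LAG_QUAD]
    )
    return masks


def percent_significant(
    fields: WTCField | list[WTCField],
    sigs: SignificanceMap | list[SignificanceMap],
    segments: list[Segment] | None = None,
) -> ScaleProfile:
    """Percentage of usable time with significant coherence, per scale and bin.

    Accepts one field/map per contiguous segment of a recording; counts are
    pooled across segments *before* dividing, so the result is a genuine
    percentage of total monitored time.  All fields must share a scale grid.
    """
    if isinstance(fields, WTCField):
        fields = [fields]
    if isinstance(sigs, SignificanceMap):
        sigs = [sigs]
    if len(fields) != len(sigs) or not fields:
        raise ValueError("need one significance map per coherence field")
    periods = fields[0].periods
    nsc = periods.size
    usable = np.zeros(nsc, dtype=np.int64)
    sig_count = {b: np.zeros(nsc, dtype=np.int64) for b in PhaseBin}
    for field, sig in zip(fields, sigs):
        if field.periods.shape != periods.shape or not np.allclose(
            field.periods, periods
        ):
            raise ValueError("all segments must share one scale grid")
        if sig.sig_mask.shape != field.r2.shape:
            raise ValueError("significance mask does not match its field")
        ok = field.outside_coi()
        usable += ok.sum(axis=0)
        bins = phase_bin_array(field.phase)
        for b in PhaseBin:
            sig_count[b] += (sig.sig_mask & ok & bins[b]).sum(axis=0)
    p = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in PhaseBin:
            vals = 100.0 * sig_count[b] / usable
            vals[usable == 0] = np.nan
            p[b] = vals
    return ScaleProfile(periods=periods, p=p, usable_count=usable, sig_count=sig_count)


def autoreg_index(
    profile: ScaleProfile,
    band: tuple[float, float] = DEFAULT_BAND,
    phase: PhaseBin = PhaseBin.IN_PHASE,
) -> AutoregIndex:
    """Mean of P(s) over the scales whose Fourier period lies in ``band``.

    Band endpoints are inclusive; scales with no usable time are excluded.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must be an increasing interval")
    in_band = (profile.periods >= lo) & (profile.periods <= hi)
    vals = profile.p[phase][in_band]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no usable scale inside the requested band")
    return AutoregIndex(
        pmean=float(vals.mean()), band=(lo, hi), phase=phase, n_scales_in_band=int(vals.size)
    )
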