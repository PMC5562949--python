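"""Morlet continuous wavelet transform, cross-wavelet and squared coherence.

The dynamic coupling between two nonstationary signals is characterized in
the time-scale plane.  For a signal :math:`x(n)` of length :math:`N` sampled
at step :math:`\\Delta t`, the continuous wavelet transform at scale
:math:`s` is

.. math::
    W_X(n, s) = \\sqrt{\\Delta t / s}\\,\\sum_{n'} x(n')\\,
        \\psi_0^*\\!\\left[(n' - n)\\,\\Delta t / s\\right],

with the Morlet mother wavelet
:math:`\\psi_0(\\eta) = \\pi^{-1/4} e^{i\\omega_0\\eta} e^{-\\eta^2/2}`
(:math:`\\omega_0 = 6` by default).  The transform is evaluated in the
Fourier domain with zero padding to the next power of two.

The cross-wavelet transform of a pair is
:math:`W_{XY} = W_X W_Y^*`; its argument is the relative phase
:math:`\\Delta\\varphi(n,s)`.  The squared wavelet coherence is the locally
smoothed, normalized cross-spectrum

.. math::
    R^2(n,s) = \\frac{|S(s^{-1} W_{XY})|^2}
                    {S(s^{-1}|W_X|^2)\\; S(s^{-1}|W_Y|^2)},

where the smoothing operator ``S`` acts along time with a Gaussian of
standard deviation equal to the scale, and across scales with a boxcar of
0.6 octaves.  Without S the ratio degenerates to exactly 1 everywhere,
which is why the smoothing is not optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WaveletParams",
    "SmoothingSpec",
    "WTCField",
    "morlet_fourier_factor",
    "scale_to_period",
    "period_to_scale",
    "cwt",
    "cross_wavelet",
    "coherence",
]


def morlet_fourier_factor(omega0: float = 6.0) -> float:
    """Ratio of Fourier period to Morlet wavelet scale, 4*pi/(w0+sqrt(2+w0^2))."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


@dataclass(frozen=True)
class WaveletParams:
    """Morlet CWT scale grid.

    Scales follow ``s_j = s0 * 2**(j*dj)`` for ``j = 0..J``.  The default
    grid starts at 2 min and spans past a 64-min Fourier period, which
    comfortably brackets the 8-32 min autoregulation band.

    Attributes
    ----------
    omega0:
        Dimensionless Morlet center frequency.
    s0:
        Smallest scale in time units (must be >= 2*dt).
    dj:
        Scale resolution in octaves (1/12 = twelve sub-octaves).
    j:
        Number of scales minus one.  If None, chosen so the largest
        Fourier period is at least ``max_period``.
    max_period:
        Target largest Fourier period (min), used only when ``j`` is None.
    """

    omega0: float = 6.0
    s0: float = 2.0
    dj: float = 1.0 / 12.0
    j: int | None = None
    max_period: float = 64.0

    def __post_init__(self) -> None:
        if self.dj <= 0:
            raise ValueError("dj must be positive")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")

    def scales(self, dt: float = 1.0) -> np.ndarray:
        if self.s0 < 2.0 * dt:
            raise ValueError("smallest scale must be at least 2*dt")
        if self.j is not None:
            jmax = self.j
        else:
            smax = self.max_period / morlet_fourier_factor(self.omega0)
            jmax = int(np.ceil(np.log2(smax / self.s0) / self.dj))
        return self.s0 * 2.0 ** (self.dj * np.arange(jmax + 1))

    def periods(self, dt: float = 1.0) -> np.ndarray:
        return scale_to_period(self.scales(dt), self.omega0)


@dataclass(frozen=True)
class SmoothingSpec:
    """Time-frequency smoothing for the coherence denominator and numerator.

    ``time_sigma_scales`` is the standard deviation of the Gaussian time
    kernel in units of the wavelet scale (1.0 matches the Morlet envelope);
    ``scale_octaves`` is the boxcar width across scales, in octaves.
    Both kernels are normalized to unit sum.
    """

    time_sigma_scales: float = 1.0
    scale_octaves: float = 0.6

    def __post_init__(self) -> None:
        if self.time_sigma_scales < 0 or self.scale_octaves < 0:
            raise ValueError("smoothing widths must be non-negative")


@dataclass
class WTCField:
    """Wavelet coherence of one signal pair on a common time/scale grid.

    Arrays are shaped (n_times, n_scales).  ``coi`` holds, per time point,
    the largest Fourier period (min) unaffected by edge effects; entries
    of the field at periods above ``coi`` are edge-contaminated.
    """

    times: np.ndarray
    scales: np.ndarray
    periods: np.ndarray
    wx: np.ndarray
    wy: np.ndarray
    wxy: np.ndarray
    r2: np.ndarray
    phase: np.ndarray
    coi: np.ndarray
    params: WaveletParams
    smoothing: SmoothingSpec

    def outside_coi(self) -> np.ndarray:
        """Boolean (n_times, n_scales) mask, true where edge effects are absent."""
        return self.periods[None, :] <= self.coi[:, None]


def scale_to_period(s, omega0: float = 6.0):
    """Convert Morlet wavelet scale to equivalent Fourier period.

    ``lambda = 4*pi*s / (omega0 + sqrt(2 + omega0**2))``; for omega0=6 the
    period is about 1.033 times the scale, so an 8-32 min period band is
    essentially an 8-32 min scale band.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("scale must be positive")
    out = morlet_fourier_factor(omega0) * s
    return float(out) if out.ndim == 0 else out


def period_to_scale(period, omega0: float = 6.0):
    period = np.asarray(period, dtype=float)
    if np.any(period <= 0):
        raise ValueError("period must be positive")
    out = period / morlet_fourier_factor(omega0)
    return float(out) if out.ndim == 0 else out


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def cwt(
    x: np.ndarray,
    dt: float,
    params: WaveletParams = WaveletParams(),
    scales: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Morlet continuous wavelet transform of a zero-mean segment.

    Parameters
    ----------
    x:
        Real, finite, detrended signal segment (length >= 2).
    dt:
        Sampling step in minutes.
    params:
        Scale grid and mother-wavelet parameters.
    scales:
        Explicit scale vector overriding ``params``'s grid.

    Returns
    -------
    w:
        Complex array (n_times, n_scales).
    scales:
        The scale vector used (min).
    coi:
        Per-time cone of influence as a maximum reliable Fourier period
        (min); the e-folding time of the Morlet envelope is sqrt(2)*s.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("cwt needs a 1-D segment of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("cwt input must be finite (gaps are segmented upstream)")
    if scales is None:
        scales = params.scales(dt)
    scales = np.asarray(scales, dtype=float)
    n = x.size
    if np.max(scales) > n * dt:
        raise ValueError(
            f"largest scale {np.max(scales):g} exceeds segment span {n * dt:g}"
        )
    npad = _next_pow2(n)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    fx = np.fft.fft(x, npad)
    arg = scales[:, None] * omega[None, :]
    # Morlet in frequency: pi^-1/4 * H(omega) * exp(-(s*omega - w0)^2 / 2),
    # normalized so |W|^2 is energy per unit scale (Torrence-Compo eq. 6)
    norm = (np.pi**-0.25) * np.sqrt(2.0 * np.pi * scales / dt)
    kernel = np.where(
        omega[None, :] > 0, np.exp(-0.5 * (arg - params.omega0) ** 2), 0.0
    )
    w = np.fft.ifft(fx[None, :] * (norm[:, None] * kernel), axis=1)[:, :n]
    dist = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    coi = morlet_fourier_factor(params.omega0) / np.sqrt(2.0) * dt * np.maximum(dist, 1e-9)
    return w.T.copy(), scales, coi


def cross_wavelet(wx: np.ndarray, wy: np.ndarray) -> np.ndarray:
    """Cross-wavelet transform ``Wx * conj(Wy)``; |.| is joint power, arg is phase."""
    wx = np.asarray(wx)
    wy = np.asarray(wy)
    if wx.shape != wy.shape:
        raise ValueError("cross_wavelet requires identically shaped transforms")
    return wx * np.conj(wy)


def _smooth_time(a: np.ndarray, scales: np.ndarray, dt: float, sigma_scales: float) -> np.ndarray:
    """Scale-dependent Gaussian smoothing along the time axis (axis 0).

    Implemented in the Fourier domain: a Gaussian of standard deviation
    ``sigma_scales * s`` in time multiplies the spectrum by
    ``exp(-(s*omega)**2 / 2)``.
    """
    n = a.shape[0]
    npad = _next_pow2(n)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    fa = np.fft.fft(a, npad, axis=0)
    filt = np.exp(-0.5 * (sigma_scales * scales[None, :] * omega[:, None]) ** 2)
    out = np.fft.ifft(fa * filt, axis=0)[:n]
    return out if np.iscomplexobj(a) else out.real


def _smooth_scale(a: np.ndarray, dj: float, octaves: float) -> np.ndarray:
    """Boxcar smoothing across scales (axis 1) over a fixed octave width.

    Fractional end weights make the effective width exactly
    ``octaves / dj`` scale steps, following the convention of published
    wavelet-coherence code.
    """
    steps = octaves / (2.0 * dj)
    if steps <= 0.5:
        return a
    frac = steps % 1.0
    nones = 2 * round(steps) - 1
    kern = np.concatenate(([frac], np.ones(nones), [frac]))
    kern /= kern.sum()
    half = kern.size // 2
    # zero-padded 'same' convolution; truncation at the scale-grid edges
    # attenuates numerator and denominator of the coherence ratio alike
    padded = np.zeros((a.shape[0], a.shape[1] + 2 * half), dtype=a.dtype)
    padded[:, half : half + a.shape[1]] = a
    out = np.empty_like(a)
    for j in range(a.shape[1]):
        out[:, j] = padded[:, j : j + kern.size] @ kern
    return out


def smooth_field(
    a: np.ndarray,
    scales: np.ndarray,
    dt: float,
    dj: float,
    spec: SmoothingSpec = SmoothingSpec(),
) -> np.ndarray:
    """Apply the full time-then-scale smoothing operator S to a field."""
    out = _smooth_time(a, scales, dt, spec.time_sigma_scales)
    return _smooth_scale(out, dj, spec.scale_octaves)


def coherence(
    x: np.ndarray,
    y: np.ndarray,
    dt: float = 1.0,
    params: WaveletParams = WaveletParams(),
    spec: SmoothingSpec = SmoothingSpec(),
    times: np.ndarray | None = None,
) -> WTCField:
    """Squared wavelet coherence and relative phase of a detrended pair.

    Returns a :class:`WTCField` holding both transforms, the cross
    spectrum, R^2 in [0, 1], the phase of the smoothed cross spectrum in
    (-pi, pi], and the cone of influence.  Points where the smoothed
    auto-power underflows are set to R^2 = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired segments must have equal length")
    wx, scales, coi = cwt(x, dt, params)
    wy, _, _ = cwt(y, dt, params)
    wxy = cross_wavelet(wx, wy)
    inv_s = 1.0 / scales[None, :]
    sxy = smooth_field(wxy * inv_s, scales, dt, params.dj, spec)
    sxx = smooth_field(np.abs(wx) ** 2 * inv_s, scales, dt, params.dj, spec)
    syy = smooth_field(np.abs(wy) ** 2 * inv_s, scales, dt, params.dj, spec)
    denom = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.abs(sxy) ** 2 / denom
    bad = ~np.isfinite(r2) | (denom <= 0)
    r2[bad] = 0.0
    if np.any(r2 > 1.0 + 1e-10) or np.any(r2 < -1e-10):
        # only float noise may be clipped; anything larger is a logic error
        raise FloatingPointError("coherence left [0, 1] beyond float tolerance")
    r2 = np.clip(r2, 0.0, 1.0)
    phase = np.angle(sxy)
    if times is None:
        times = np.arange(x.size, dtype=float) * dt
    return WTCField(
        times=np.asarray(times, dtype=float),
        scales=scales,
        periods=scale_to_period(scales, params.omega0),
        wx=wx,
        wy=wy,
        wxy=wxy,
        r2=r2,
        phase=phase,
        coi=coi,
        params=params,
        smoothing=spec,
    )
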