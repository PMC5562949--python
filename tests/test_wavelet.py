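"""Morlet CWT, cross-wavelet and coherence.

The independent oracle here is a literal direct-summation Morlet transform
(the defining convolution sum, evaluated with explicit loops over scales)
and an equally literal time/scale smoothing, against which the FFT-based
implementation is compared away from the segment edges.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from autoregwtc.wavelet import (
    SmoothingSpec,
    WaveletParams,
    coherence,
    cross_wavelet,
    cwt,
    morlet_fourier_factor,
    period_to_scale,
    scale_to_period,
)

OMEGA0 = 6.0


def brute_force_cwt(x, dt, scales, omega0=OMEGA0):
    """Direct evaluation of the defining convolution sum, no FFT involved.

    Valid away from the edges (where zero padding in the FFT path and the
    truncated sum here both see only zeros beyond the data).
    """
    n = len(x)
    tt = np.arange(n) * dt
    out = np.empty((n, len(scales)), complex)
    for j, s in enumerate(scales):
        for i in range(n):
            eta = (tt - tt[i]) / s
            psi = (np.pi**-0.25) * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)
            out[i, j] = np.sqrt(dt / s) * np.sum(x * np.conj(psi))
    return out


class TestScalePeriod:
    def test_closed_form_at_unit_scale(self):
        assert scale_to_period(1.0) == pytest.approx(4 * np.pi / (6 + np.sqrt(38)))
        assert scale_to_period(1.0) == pytest.approx(1.0330, abs=1e-4)

    def test_monotone_and_inverse(self):
        s = np.linspace(0.5, 80, 200)
        lam = scale_to_period(s)
        assert np.all(np.diff(lam) > 0)
        np.testing.assert_allclose(period_to_scale(lam), s)

    def test_band_edges_match_stated_frequency_range(self):
        # 8-32 min periods correspond to ~0.002 down to ~0.0005 Hz
        assert 1.0 / (32 * 60) == pytest.approx(0.00052, abs=3e-5)
        f_hi = 1.0 / (8 * 60)
        assert f_hi == pytest.approx(0.00208, abs=3e-5)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            scale_to_period(0.0)


class TestCwt:
    def test_zero_input_zero_output(self, fast_wavelet):
        w, _, _ = cwt(np.zeros(128), 1.0, fast_wavelet)
        np.testing.assert_array_equal(w, 0.0)

    def test_linearity(self, fast_wavelet, rng):
        x = rng.normal(0, 1, 256)
        w1, _, _ = cwt(x, 1.0, fast_wavelet)
        w3, _, _ = cwt(3.5 * x, 1.0, fast_wavelet)
        np.testing.assert_allclose(w3, 3.5 * w1, rtol=1e-10)

    def test_sinusoid_power_peaks_at_matching_period(self):
        params = WaveletParams()
        n = 2048
        x = np.sin(2 * np.pi * np.arange(n) / 16.0)
        w, scales, _ = cwt(x, 1.0, params)
        periods = params.periods(1.0)
        jpeak = int(np.argmax(np.abs(w[n // 2])))
        # within one scale step of the true period
        assert abs(np.log2(periods[jpeak] / 16.0)) <= params.dj + 1e-12

    def test_scale_beyond_segment_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            cwt(np.zeros(32), 1.0, WaveletParams())

    def test_coi_symmetric_and_linear_from_edges(self, fast_wavelet):
        _, _, coi = cwt(np.zeros(200), 1.0, fast_wavelet)
        np.testing.assert_allclose(coi, coi[::-1])
        interior = coi[1:100]
        np.testing.assert_allclose(np.diff(interior), np.diff(interior)[0])

    def test_agrees_with_direct_summation(self, rng):
        # s0 = 4*dt keeps the wavelet's pass band clear of Nyquist, where
        # the sampled time-domain sum and the band-limited FFT kernel are
        # legitimately different discretizations
        params = WaveletParams(s0=4.0, dj=1.0 / 3.0, j=5)
        x = rng.normal(0, 1, 256)
        scales = params.scales(1.0)  # 4 .. 12.7 min
        w, _, _ = cwt(x, 1.0, params)
        ref = brute_force_cwt(x, 1.0, scales)
        # interior points: > 8 envelope widths of the largest scale from edges
        interior = slice(104, 152)
        err = np.max(np.abs(w[interior] - ref[interior]))
        assert err / np.max(np.abs(ref[interior])) < 1e-6


class TestCrossWavelet:
    def test_self_cross_is_power(self, fast_wavelet, rng):
        x = rng.normal(0, 1, 128)
        w, _, _ = cwt(x, 1.0, fast_wavelet)
        wxx = cross_wavelet(w, w)
        np.testing.assert_allclose(wxx.imag, 0.0, atol=1e-12)
        np.testing.assert_allclose(wxx.real, np.abs(w) ** 2)

    def test_conjugate_symmetry_under_swap(self, fast_wavelet, rng):
        x = rng.normal(0, 1, 128)
        y = rng.normal(0, 1, 128)
        wx, _, _ = cwt(x, 1.0, fast_wavelet)
        wy, _, _ = cwt(y, 1.0, fast_wavelet)
        np.testing.assert_allclose(
            cross_wavelet(wx, wy), np.conj(cross_wavelet(wy, wx))
        )

    def test_antiphase_sinusoids_have_phase_pi(self):
        params = WaveletParams()
        n = 1024
        x = np.sin(2 * np.pi * np.arange(n) / 16.0)
        wx, scales, _ = cwt(x, 1.0, params)
        wy, _, _ = cwt(-x, 1.0, params)
        j = int(np.argmin(np.abs(params.periods(1.0) - 16.0)))
        phase = np.angle(cross_wavelet(wx, wy)[n // 2, j])
        assert abs(abs(phase) - np.pi) < 1e-6

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cross_wavelet(np.zeros((3, 2)), np.zeros((2, 3)))


class TestCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.normal(0, 1, 512)
        f = coherence(x, x.copy())
        assert f.r2[f.outside_coi()].min() >= 0.999
        assert np.max(np.abs(f.phase[f.outside_coi()])) < 1e-6

    def test_sign_flip_gives_antiphase(self, rng):
        x = rng.normal(0, 1, 512)
        f = coherence(x, -x)
        ok = f.outside_coi()
        assert f.r2[ok].min() >= 0.999
        assert np.min(np.abs(f.phase[ok])) > np.pi - 1e-6

    def test_unsmoothed_coherence_degenerates_to_one(self, rng):
        # the regression test that the smoothing operator is doing its job
        x = rng.normal(0, 1, 256)
        y = rng.normal(0, 1, 256)
        spec = SmoothingSpec(time_sigma_scales=0.0, scale_octaves=0.0)
        f = coherence(x, y, spec=spec)
        np.testing.assert_allclose(f.r2, 1.0, atol=1e-6)
        f_smoothed = coherence(x, y)
        assert f_smoothed.r2[f_smoothed.outside_coi()].mean() < 0.9

    @given(seed=st.integers(0, 40))
    def test_phase_antisymmetry_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 256)
        y = rng.normal(0, 1, 256)
        params = WaveletParams(dj=1.0 / 6.0)
        fxy = coherence(x, y, params=params)
        fyx = coherence(y, x, params=params)
        # away from exact zeros of the smoothed cross spectrum the angles negate
        np.testing.assert_allclose(
            np.sin(fxy.phase + fyx.phase), 0.0, atol=1e-8
        )
        np.testing.assert_allclose(fxy.r2, fyx.r2, atol=1e-12)

    def test_r2_bounded(self, rng):
        x = rng.normal(0, 1, 300)
        y = 0.5 * x + rng.normal(0, 1, 300)
        f = coherence(x, y)
        assert f.r2.min() >= 0.0 and f.r2.max() <= 1.0

    def test_agrees_with_literal_smoothing_oracle(self, rng):
        """R^2 recomputed with naive loop-based smoothing matches."""
        params = WaveletParams(s0=2.0, dj=1.0 / 4.0, j=8)
        spec = SmoothingSpec()
        n = 128
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        f = coherence(x, y, 1.0, params, spec)
        scales = f.scales

        npad = 1 << int(n - 1).bit_length()

        def smooth_ref(a):
            # time: explicit circular Gaussian on the zero-padded axis
            ap = np.zeros((npad, a.shape[1]), dtype=a.dtype)
            ap[:n] = a
            out_t = np.empty_like(ap)
            pos = np.arange(npad)
            for j, s in enumerate(scales):
                d = np.abs(pos[:, None] - pos[None, :])
                d = np.minimum(d, npad - d).astype(float)
                k = np.exp(-0.5 * (d / s) ** 2)
                k /= k.sum(axis=1, keepdims=True)
                out_t[:, j] = k @ ap[:, j]
            out_t = out_t[:n]
            # scale: fractional-end boxcar, zero padded
            steps = spec.scale_octaves / (2 * params.dj)
            frac = steps % 1.0
            kern = np.concatenate(([frac], np.ones(2 * round(steps) - 1), [frac]))
            kern /= kern.sum()
            half = kern.size // 2
            padded = np.zeros((n, scales.size + 2 * half), dtype=a.dtype)
            padded[:, half : half + scales.size] = out_t
            out = np.empty((n, scales.size), dtype=a.dtype)
            for j in range(scales.size):
                out[:, j] = padded[:, j : j + kern.size] @ kern
            return out

        inv_s = 1.0 / scales[None, :]
        num = np.abs(smooth_ref(f.wxy * inv_s)) ** 2
        den = smooth_ref(np.abs(f.wx) ** 2 * inv_s) * smooth_ref(
            np.abs(f.wy) ** 2 * inv_s
        )
        ref = num / den
        ok = f.outside_coi()
        assert np.max(np.abs(f.r2[ok] - ref[ok])) < 0.02
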