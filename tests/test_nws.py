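"""Wiener-spectrum estimation: Parseval contract, radial binning,
normalization invariances and the blur signature."""

import numpy as np
import pytest

from mammoblur.errors import PlacementError, ShapeError
from mammoblur.io import Mammogram
from mammoblur.nws import (
    NwsConfig,
    NwsSpectrum,
    compute_nws,
    extract_roi_spectrum,
    normalize_spectrum,
    power_spectrum_2d,
    radial_average,
)
from mammoblur.synthetic import line_psf, power_law_texture


def brute_force_radial(power2d, fu, fv, df, max_freq):
    """Independent double-loop binning oracle (same rule: nearest bin
    center, DC-neighborhood bin 0 excluded)."""
    n_bins = int(np.floor(max_freq / df + 0.5))
    sums = np.zeros(n_bins + 1)
    counts = np.zeros(n_bins + 1)
    for i in range(len(fu)):
        for j in range(len(fv)):
            r = np.hypot(fu[i], fv[j])
            k = int(np.floor(r / df + 0.5))
            if 1 <= k <= n_bins:
                sums[k] += power2d[i, j]
                counts[k] += 1
    vals = np.full(n_bins, np.nan)
    good = counts[1:] > 0
    vals[good] = sums[1:][good] / counts[1:][good]
    return vals


class TestPowerSpectrum:
    def test_constant_roi_zero_power(self):
        power, _, _ = power_spectrum_2d(np.full((32, 32), 5.0), NwsConfig(), 0.05)
        assert np.allclose(power, 0.0)

    @pytest.mark.parametrize("window_fn", ["hann", "hamming", "tukey"])
    def test_parseval_identity_every_taper(self, window_fn):
        """Spectral integral == variance of the detrended, tapered ROI
        divided by the mean squared taper — exactly, for every taper."""
        from scipy.signal import windows as w

        rng = np.random.default_rng(3)
        roi = rng.normal(size=(64, 64))
        cfg = NwsConfig(window_fn=window_fn)
        power, fu, fv = power_spectrum_2d(roi, cfg, 0.05)
        df = fu[1] - fu[0]
        integral = power.sum() * df * df
        taper1 = {"hann": w.hann(64, sym=False), "hamming": w.hamming(64, sym=False),
                  "tukey": w.tukey(64, alpha=0.5, sym=False)}[window_fn]
        taper = np.outer(taper1, taper1)
        detrended = roi - roi.mean()
        expected = np.mean((detrended * taper) ** 2) / np.mean(taper**2)
        assert integral == pytest.approx(expected, rel=1e-9)

    def test_white_noise_recovers_variance(self):
        rng = np.random.default_rng(5)
        sigma = 0.7
        integrals = []
        for _ in range(10):
            roi = rng.normal(0, sigma, size=(128, 128))
            power, fu, _ = power_spectrum_2d(roi, NwsConfig(), 0.05)
            df = fu[1] - fu[0]
            integrals.append(power.sum() * df * df)
        assert np.mean(integrals) == pytest.approx(sigma**2, rel=0.02)

    def test_sinusoid_concentrates_at_its_frequency(self):
        n, dx = 64, 0.05
        f0 = 8 / (n * dx)  # on the frequency lattice
        x = np.arange(n) * dx
        roi = np.tile(np.sin(2 * np.pi * f0 * x), (n, 1))
        power, fu, fv = power_spectrum_2d(roi, NwsConfig(), dx)
        # the 2-D taper spreads each spectral line over +-1 lattice
        # neighbors on both axes, so the conjugate concentration is
        # measured on 3x3 neighborhoods around (0, +-f0)
        k = 8
        near = np.zeros_like(power, dtype=bool)
        for kk in (k, n - k):
            for di in (-1, 0, 1):
                near[di % n, kk - 1 : kk + 2] = True
        assert power[near].sum() / power.sum() > 0.99

    def test_shape_and_value_errors(self):
        with pytest.raises(ShapeError):
            power_spectrum_2d(np.zeros((8, 8)), NwsConfig(), 0.05)  # too small
        with pytest.raises(ShapeError):
            power_spectrum_2d(np.zeros((32, 16)), NwsConfig(), 0.05)  # not square
        bad = np.zeros((32, 32))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            power_spectrum_2d(bad, NwsConfig(), 0.05)

    def test_poly2_detrend_removes_gradient(self):
        r, c = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        ramp = 0.01 * r + 0.02 * c + 1e-4 * r * c
        cfg = NwsConfig(detrend="poly2")
        power, fu, _ = power_spectrum_2d(ramp, cfg, 0.05)
        df = fu[1] - fu[0]
        assert power.sum() * df * df < 1e-12


class TestRadialAverage:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, dx = 32, 0.05
        power = rng.random((n, n))
        f = np.fft.fftfreq(n, d=dx)
        cfg = NwsConfig()
        spec = radial_average(power, (f, f), cfg)
        df = abs(f[1] - f[0])
        oracle = brute_force_radial(power, f, f, df, np.max(np.abs(f)))
        assert np.array_equal(spec.values, oracle[: len(spec.values)])

    def test_isotropic_gaussian_profile(self):
        n, dx = 128, 0.05
        f = np.fft.fftfreq(n, d=dx)
        uu, vv = np.meshgrid(f, f, indexing="ij")
        sigma = 3.0
        power = np.exp(-(uu**2 + vv**2) / (2 * sigma**2))
        spec = radial_average(power, (f, f), NwsConfig())
        profile = np.exp(-(spec.freqs_mm**2) / (2 * sigma**2))
        rms = np.sqrt(np.mean((spec.values - profile) ** 2))
        assert rms < 0.01

    def test_dc_only_power_gives_zero(self):
        n = 32
        f = np.fft.fftfreq(n, d=0.05)
        power = np.zeros((n, n))
        power[0, 0] = 42.0
        spec = radial_average(power, (f, f), NwsConfig())
        assert np.allclose(spec.values, 0.0)

    def test_empty_bin_interpolated_with_warning(self):
        n = 32
        f = np.fft.fftfreq(n, d=0.05)
        power = np.ones((n, n))
        cfg = NwsConfig(bin_width_mm=0.05)  # finer than the native lattice
        with pytest.warns(UserWarning, match="empty"):
            spec = radial_average(power, (f, f), cfg)
        assert np.isfinite(spec.values).all()


class TestNormalization:
    def test_unit_area_integrates_to_one(self):
        rng = np.random.default_rng(7)
        spec = compute_nws(rng.normal(size=(64, 64)), 0.05)
        assert spec.values.sum() * spec.bin_width == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        roi = rng.normal(10, 2, size=(64, 64))
        a = compute_nws(roi, 0.05)
        b = compute_nws(roi * 137.0, 0.05)
        assert np.allclose(a.values, b.values, rtol=1e-9, atol=1e-12)

    def test_zero_spectrum_flagged_degenerate(self):
        raw = NwsSpectrum(freqs_mm=np.arange(1, 5.0), values=np.zeros(4))
        out = normalize_spectrum(raw, None, NwsConfig())
        assert out.degenerate and np.all(out.values == 0.0)

    def test_mean_square_mode(self):
        raw = NwsSpectrum(freqs_mm=np.arange(1, 5.0), values=np.array([2.0, 4.0, 6.0, 8.0]))
        out = normalize_spectrum(raw, {"mean": 2.0}, NwsConfig(normalization="mean_square"))
        assert np.allclose(out.values, np.array([2.0, 4.0, 6.0, 8.0]) / 4.0)


class TestRoiExtraction:
    def test_mask_coverage_precondition(self, sharp_phantom):
        m = sharp_phantom.mammogram
        mask = np.zeros(m.shape, dtype=bool)
        mask[:, :600] = True  # right part of a centered ROI uncovered
        with pytest.raises(PlacementError):
            extract_roi_spectrum(m.replace_pixels(m.pixels.astype(float)), mask, (400, 500), 256)
        with pytest.raises(PlacementError):
            extract_roi_spectrum(m.replace_pixels(m.pixels.astype(float)), mask, (1100, 0), 256)

    def test_stationarity_of_iid_noise(self):
        rng = np.random.default_rng(9)
        m = Mammogram(rng.normal(size=(600, 600)), 0.05, "L", "CC")
        mask = np.ones((600, 600), dtype=bool)
        a = extract_roi_spectrum(m, mask, (0, 0), 256)
        b = extract_roi_spectrum(m, mask, (300, 300), 256)
        for lo, hi in [(1.0, 5.0), (5.0, 9.0)]:
            assert a.band_integral(lo, hi) == pytest.approx(b.band_integral(lo, hi), rel=0.05)

    def test_blur_lowers_midfrequency_band(self):
        """Motion blur drains the 1-3 mm^-1 band of the unit-area nWS."""
        from scipy.signal import fftconvolve

        diffs = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            texture = 0.75 + 0.12 * power_law_texture(256, 3.0, rng)
            noise = rng.standard_normal((256, 256))
            sharp = texture + 0.01 * np.sqrt(np.clip(texture, 0, None)) * noise
            blurred_t = fftconvolve(texture, line_psf(8.0, 30.0), mode="same")
            blurred = blurred_t + 0.01 * np.sqrt(np.clip(blurred_t, 0, None)) * noise
            s = compute_nws(sharp, 0.05)
            b = compute_nws(blurred, 0.05)
            diffs.append(s.band_integral(1, 3) - b.band_integral(1, 3))
        assert all(d > 0 for d in diffs)
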