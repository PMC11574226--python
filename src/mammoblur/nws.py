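"""Normalized Wiener spectrum (nWS) estimation.

The Wiener (noise-power) spectrum of a square region is estimated the way
it is done in mammographic physics: the region is detrended, multiplied by
an edge taper to suppress spectral ringing, Fourier transformed, and the
squared modulus is scaled so that the 2-D spectral integral equals the
variance of the detrended, tapered region (Parseval contract).  A radial
average over annuli of constant |f| collapses the 2-D spectrum to a 1-D
profile, and a final normalization puts every spectrum on a common absolute
scale so that spectra from different detectors, doses and vendors become
comparable.

Units: spatial frequency in mm^-1; with ``unit_area`` normalization the
spectrum integrates to 1 over its frequency axis, making it a density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import windows as _windows

from .errors import ConfigurationError, PlacementError, ShapeError
from .io import Mammogram

MIN_ROI_PX = 16

_WINDOW_FNS = {
    "hann": lambda n: _windows.hann(n, sym=False),
    "hamming": lambda n: _windows.hamming(n, sym=False),
    "tukey": lambda n: _windows.tukey(n, alpha=0.5, sym=False),
}


@dataclass
class NwsConfig:
    """Spectrum-estimation settings.

    window_fn
        Edge taper; Hann by default (the standard NPS choice).
    detrend
        ``mean`` subtracts the ROI mean; ``poly2`` removes a least-squares
        2nd-order polynomial surface (for breast-thickness gradients).
    bin_width_mm
        Radial bin width, or ``None`` for the native frequency resolution
        1/(N*dx) of the ROI.
    max_freq_mm
        Highest retained bin center; ``None`` means the axis Nyquist
        1/(2*dx) (corner frequencies beyond it are discarded).
    normalization
        ``unit_area`` divides by the spectral integral (dose- and
        vendor-independent absolute scale); ``mean_square`` divides by the
        squared mean ROI signal (the classical nNPS convention).
    """

    window_fn: str = "hann"
    detrend: str = "mean"
    bin_width_mm: float | None = None
    max_freq_mm: float | None = None
    normalization: str = "unit_area"

    def __post_init__(self) -> None:
        if self.window_fn not in _WINDOW_FNS:
            raise ConfigurationError(f"unknown window_fn {self.window_fn!r}")
        if self.detrend not in ("mean", "poly2"):
            raise ConfigurationError(f"unknown detrend {self.detrend!r}")
        if self.bin_width_mm is not None and not self.bin_width_mm > 0:
            raise ConfigurationError("bin_width_mm must be positive")
        if self.normalization not in ("unit_area", "mean_square"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")


@dataclass
class NwsSpectrum:
    """Radially averaged (normalized) noise-power spectrum.

    ``freqs_mm`` are strictly increasing bin centers in mm^-1;
    ``values`` the non-negative spectral density at each bin.
    """

    freqs_mm: np.ndarray
    values: np.ndarray
    degenerate: bool = False
    roi_origin: tuple[int, int] = (0, 0)
    roi_size_px: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs_mm = np.asarray(self.freqs_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs_mm.shape != self.values.shape:
            raise ShapeError("freqs and values must have equal length")
        if len(self.freqs_mm) and np.any(np.diff(self.freqs_mm) <= 0):
            raise ShapeError("frequency axis must be strictly increasing")

    @property
    def bin_width(self) -> float:
        return float(self.freqs_mm[1] - self.freqs_mm[0]) if len(self.freqs_mm) > 1 else 0.0

    def band_integral(self, f_lo: float, f_hi: float) -> float:
        """Integral of the spectrum over [f_lo, f_hi] (rectangle rule)."""
        sel = (self.freqs_mm >= f_lo) & (self.freqs_mm <= f_hi)
        return float(self.values[sel].sum() * self.bin_width)


def _detrend(roi: np.ndarray, method: str) -> np.ndarray:
    if method == "mean":
        return roi - roi.mean()
    # poly2: least-squares 2nd-order surface in (r, c)
    n = roi.shape[0]
    r, c = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = (r - r.mean()) / n
    c = (c - c.mean()) / n
    basis = np.column_stack(
        [np.ones(n * n), r.ravel(), c.ravel(), (r * r).ravel(), (r * c).ravel(), (c * c).ravel()]
    )
    coef, *_ = np.linalg.lstsq(basis, roi.ravel(), rcond=None)
    return roi - (basis @ coef).reshape(n, n)


def power_spectrum_2d(
    roi: np.ndarray, cfg: NwsConfig, pixel_spacing_mm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D noise-power spectrum of a square ROI.

    Returns ``(power, fu, fv)`` with ``power[i, j]`` the spectral density at
    frequency ``(fu[i], fv[j])`` (numpy fft ordering, DC at index 0).  The
    scaling is ``dx*dy / (Nx*Ny*mean(W^2))`` so that
    ``power.sum() * df^2`` equals the variance of the detrended, tapered ROI
    divided by the mean squared taper — i.e. the spectral integral matches
    the region's detrended-windowed variance.
    """
    roi = np.asarray(roi, dtype=np.float64)
    if roi.ndim != 2 or roi.shape[0] != roi.shape[1]:
        raise ShapeError(f"ROI must be square 2-D, got shape {roi.shape}")
    n = roi.shape[0]
    if n < MIN_ROI_PX:
        raise ShapeError(f"ROI side must be >= {MIN_ROI_PX} px, got {n}")
    if not np.isfinite(roi).all():
        raise ValueError("ROI contains NaN or Inf")
    dx = float(pixel_spacing_mm)

    detrended = _detrend(roi, cfg.detrend)
    w1 = _WINDOW_FNS[cfg.window_fn](n)
    taper = np.outer(w1, w1)
    tapered = detrended * taper
    spec = np.fft.fft2(tapered)
    power = (np.abs(spec) ** 2) * (dx * dx) / (n * n * np.mean(taper**2))
    f = np.fft.fftfreq(n, d=dx)
    return power, f.copy(), f.copy()


def radial_average(
    power2d: np.ndarray,
    freq_grids: tuple[np.ndarray, np.ndarray],
    cfg: NwsConfig,
) -> NwsSpectrum:
    """Collapse a 2-D power spectrum to its radial profile.

    Each sample at frequency (u, v) is assigned to the bin whose center
    ``k * df`` is nearest to ``sqrt(u^2 + v^2)``; the bin value is the mean
    of its samples.  The DC sample is excluded (it carries only detrend
    residual) and bins whose centers exceed ``max_freq`` are dropped.  An
    empty interior bin is filled by linear interpolation of its neighbors
    with a warning.
    """
    fu, fv = freq_grids
    native_df = float(abs(fu[1] - fu[0]))
    df = cfg.bin_width_mm if cfg.bin_width_mm is not None else native_df
    nyquist = float(np.max(np.abs(fu)))
    max_freq = cfg.max_freq_mm if cfg.max_freq_mm is not None else nyquist

    uu, vv = np.meshgrid(fu, fv, indexing="ij")
    r = np.sqrt(uu * uu + vv * vv)
    # half-open bins [ (k-0.5)df, (k+0.5)df ) centered at k*df; floor(+0.5)
    # rather than rint so ties at bin edges resolve upward, deterministically
    idx = np.floor(r / df + 0.5).astype(np.int64)

    n_bins = int(np.floor(max_freq / df + 0.5))
    if n_bins < 1:
        raise ConfigurationError("max_freq too small: no bins remain")
    flat_idx = idx.ravel()
    flat_pow = power2d.ravel()
    keep = (flat_idx >= 1) & (flat_idx <= n_bins)  # bin 0 (DC neighborhood) excluded
    sums = np.bincount(flat_idx[keep], weights=flat_pow[keep], minlength=n_bins + 1)
    counts = np.bincount(flat_idx[keep], minlength=n_bins + 1)

    freqs = np.arange(1, n_bins + 1) * df
    values = np.full(n_bins, np.nan)
    nonzero = counts[1:] > 0
    values[nonzero] = sums[1:][nonzero] / counts[1:][nonzero]
    if not nonzero.all():
        warnings.warn(
            f"{(~nonzero).sum()} empty radial bins filled by interpolation", stacklevel=2
        )
        good = np.flatnonzero(nonzero)
        if good.size == 0:
            raise ConfigurationError("all radial bins are empty")
        values = np.interp(np.arange(n_bins), good, values[good])
    return NwsSpectrum(freqs_mm=freqs, values=values)


def normalize_spectrum(
    raw: NwsSpectrum, roi_stats: dict | None = None, cfg: NwsConfig | None = None
) -> NwsSpectrum:
    """Put a radial spectrum on the configured absolute scale.

    ``unit_area``: divide by the spectral integral so the result integrates
    to exactly 1 — invariant to any global intensity rescaling of the ROI.
    ``mean_square``: divide by the squared mean ROI signal (requires
    ``roi_stats['mean']``).  A zero-power spectrum is flagged degenerate
    (all zeros) rather than raising.
    """
    cfg = cfg or NwsConfig()
    df = raw.bin_width
    if cfg.normalization == "unit_area":
        total = float(raw.values.sum() * df)
        if total <= 0:
            return replace(raw, values=np.zeros_like(raw.values), degenerate=True)
        return replace(raw, values=raw.values / total, degenerate=False)
    if roi_stats is None or "mean" not in roi_stats:
        raise ConfigurationError("mean_square normalization requires roi_stats['mean']")
    denom = float(roi_stats["mean"]) ** 2
    if denom <= 0:
        return replace(raw, values=np.zeros_like(raw.values), degenerate=True)
    return replace(raw, values=raw.values / denom, degenerate=False)


def compute_nws(
    roi: np.ndarray,
    pixel_spacing_mm: float,
    cfg: NwsConfig | None = None,
    origin: tuple[int, int] = (0, 0),
) -> NwsSpectrum:
    """Full nWS of one square ROI: spectrum, radial average, normalization."""
    cfg = cfg or NwsConfig()
    power, fu, fv = power_spectrum_2d(roi, cfg, pixel_spacing_mm)
    raw = radial_average(power, (fu, fv), cfg)
    spec = normalize_spectrum(raw, {"mean": float(np.mean(roi))}, cfg)
    return replace(spec, roi_origin=tuple(origin), roi_size_px=roi.shape[0])


def extract_roi_spectrum(
    m: Mammogram,
    mask: np.ndarray,
    origin: tuple[int, int],
    size_px: int = 1000,
    cfg: NwsConfig | None = None,
    min_mask_fraction: float = 0.95,
) -> NwsSpectrum:
    """nWS of a manually placed square ROI on a preprocessed mammogram.

    The ROI must lie fully inside the image and cover the analysis mask by
    at least ``min_mask_fraction`` (default 95%); otherwise a
    :class:`PlacementError` is raised.
    """
    r0, c0 = int(origin[0]), int(origin[1])
    h, w = m.shape
    if r0 < 0 or c0 < 0 or r0 + size_px > h or c0 + size_px > w:
        raise PlacementError(f"ROI at {origin} size {size_px} exceeds image {m.shape}")
    coverage = float(mask[r0 : r0 + size_px, c0 : c0 + size_px].mean())
    if coverage < min_mask_fraction:
        raise PlacementError(
            f"ROI covers the analysis mask by {coverage:.3f} < {min_mask_fraction}"
        )
    roi = np.asarray(m.pixels[r0 : r0 + size_px, c0 : c0 + size_px], dtype=np.float64)
    return compute_nws(roi, m.pixel_spacing_mm, cfg, origin=(r0, c0))
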