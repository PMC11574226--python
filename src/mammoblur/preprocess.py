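"""Mammogram standardization and breast-interior segmentation.

Every image is brought onto a square canvas by laterality-aware zero
padding (the breast stays anchored to its chest-wall edge), intensities are
normalized to [0, 1], and an analysis mask is derived that keeps the breast
interior while excluding background, the skin line and — optionally — the
pectoralis muscle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, DegenerateImageWarning, SegmentationError
from .io import Mammogram


@dataclass
class PreprocessConfig:
    """Canvas and segmentation settings.

    canvas_size_px
        Side of the square canvas.  ``None`` selects
        ``max(4915, input dimensions)`` — the clinical full-resolution
        default that grows, never crops.  An explicitly pinned canvas
        smaller than the input raises instead of cropping.
    skin_margin_mm
        Depth of the inward erosion that strips the bright skin line
        (2 mm ~ 40 px at 0.05 mm pitch).
    """

    canvas_size_px: int | None = None
    skin_margin_mm: float = 2.0
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.05

    CLINICAL_CANVAS_PX = 4915

    def __post_init__(self) -> None:
        if self.canvas_size_px is not None and self.canvas_size_px < 2:
            raise ConfigurationError("canvas_size_px must be >= 2")
        if self.skin_margin_mm < 0:
            raise ConfigurationError("skin_margin_mm must be non-negative")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigurationError(f"unknown threshold_method {self.threshold_method!r}")
        if not 0.0 <= self.fixed_threshold <= 1.0:
            raise ConfigurationError("fixed_threshold must lie in [0, 1]")


@dataclass
class AnalysisMask:
    """Boolean raster of analyzable breast-interior pixels on the padded
    canvas; ``provenance`` records whether it was segmented here or supplied
    externally."""

    mask: np.ndarray
    provenance: str = "segmented"


def pad_to_canvas(m: Mammogram, cfg: PreprocessConfig | None = None) -> Mammogram:
    """Zero-pad a mammogram onto a square canvas.

    New columns go on the side away from the chest wall: to the right for
    laterality L, to the left for R.  New rows go at the bottom.  Original
    pixel values are untouched.
    """
    cfg = cfg or PreprocessConfig()
    h, w = m.shape
    if cfg.canvas_size_px is None:
        canvas = max(cfg.CLINICAL_CANVAS_PX, h, w)
    else:
        canvas = cfg.canvas_size_px
        if h > canvas or w > canvas:
            raise ConfigurationError(
                f"input {h}x{w} exceeds canvas {canvas}; enlarge canvas_size_px "
                "(padding never crops)"
            )
    if (h, w) == (canvas, canvas):
        return m
    out = np.zeros((canvas, canvas), dtype=m.pixels.dtype)
    if m.laterality == "L":
        out[:h, :w] = m.pixels
    else:
        out[:h, canvas - w :] = m.pixels
    return m.replace_pixels(out)


def normalize_intensity(m: Mammogram) -> Mammogram:
    """Affinely map intensities to [0, 1]; min -> 0, max -> 1.

    A constant raster is degenerate: it maps to all zeros and emits a
    :class:`DegenerateImageWarning`.
    """
    pixels = m.pixels.astype(np.float64)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        warnings.warn(
            "constant-intensity raster; normalization is degenerate (all zeros)",
            DegenerateImageWarning,
            stacklevel=2,
        )
        return m.replace_pixels(np.zeros_like(pixels))
    return m.replace_pixels((pixels - lo) / (hi - lo))


def segment_breast(
    m: Mammogram,
    cfg: PreprocessConfig | None = None,
    pectoralis_mask: np.ndarray | None = None,
) -> AnalysisMask:
    """Segment the breast interior of a normalized, padded mammogram.

    Pipeline: foreground threshold (Otsu by default) -> keep the largest
    connected foreground region -> fill holes -> erode inward by
    ``skin_margin_mm`` to drop the skin line -> subtract the supplied
    pectoralis mask -> keep the largest remaining component.
    """
    cfg = cfg or PreprocessConfig()
    pixels = np.asarray(m.pixels, dtype=np.float64)
    if cfg.threshold_method == "otsu":
        vals = pixels.ravel()
        if np.ptp(vals) == 0:
            raise SegmentationError("image is constant; no foreground to segment")
        thr = threshold_otsu(pixels)
    else:
        thr = cfg.fixed_threshold
    fg = pixels > thr
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding")

    fg = _largest_component(fg)
    fg = ndimage.binary_fill_holes(fg)

    margin_px = int(round(cfg.skin_margin_mm / m.pixel_spacing_mm))
    if margin_px > 0:
        # euclidean distance transform is much faster than a 40-px disk erosion
        inner = ndimage.distance_transform_edt(fg) > margin_px
    else:
        inner = fg
    if pectoralis_mask is not None:
        if pectoralis_mask.shape != inner.shape:
            raise ConfigurationError(
                f"pectoralis mask shape {pectoralis_mask.shape} != canvas {inner.shape}"
            )
        inner = inner & ~pectoralis_mask.astype(bool)
    if not inner.any():
        raise SegmentationError("segmentation produced an empty analysis mask")
    inner = _largest_component(inner)
    provenance = "segmented" if pectoralis_mask is None else "segmented+supplied_pectoralis"
    return AnalysisMask(mask=inner, provenance=provenance)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def pectoralis_corner_heuristic(
    m: Mammogram, frac_rows: float = 0.25, frac_cols: float = 0.2
) -> np.ndarray:
    """Synthetic stand-in for a dedicated pectoralis segmentation model.

    Marks a triangular region in the chest-wall top corner of an MLO view
    (where the pectoralis projects); returns an all-false mask for CC views.
    This geometric heuristic is a deliberately crude placeholder — supply a
    real mask for clinical work.
    """
    h, w = m.shape
    mask = np.zeros((h, w), dtype=bool)
    if m.view != "MLO":
        return mask
    rows = int(h * frac_rows)
    cols = int(w * frac_cols)
    if rows < 1 or cols < 1:
        return mask
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    tri = (rr / rows + cc / cols) < 1.0
    if m.laterality == "L":
        mask[:rows, :cols] = tri
    else:
        mask[:rows, w - cols :] = tri[:, ::-1]
    return mask


def preprocess(
    m: Mammogram,
    cfg: PreprocessConfig | None = None,
    pectoralis_mask: np.ndarray | None = None,
) -> tuple[Mammogram, AnalysisMask]:
    """Pad, normalize and segment in one call.

    A pectoralis mask, if given, is aligned to the original (pre-padding)
    raster and is padded here alongside the image.
    """
    cfg = cfg or PreprocessConfig()
    padded = pad_to_canvas(m, cfg)
    if pectoralis_mask is not None and pectoralis_mask.shape != padded.shape:
        pm = Mammogram(
            pixels=pectoralis_mask.astype(np.uint8),
            pixel_spacing_mm=m.pixel_spacing_mm,
            laterality=m.laterality,
            view=m.view,
        )
        pectoralis_mask = pad_to_canvas(pm, cfg).pixels.astype(bool)
    normalized = normalize_intensity(padded)
    mask = segment_breast(normalized, cfg, pectoralis_mask)
    return normalized, mask
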