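"""Synthetic mammographic phantoms with ground-truth motion blur.

Each phantom is a breast-shaped (half-ellipse) support on a dark
background, filled with correlated fibroglandular-like texture — a
power-law-filtered Gaussian field with spectral exponent ``texture_beta``
— plus quantum (Poisson-like) noise at mammographic pixel pitch.  Motion
blur is applied locally inside ground-truth polygons by convolution with a
unit-sum line point-spread function, blended smoothly at the region
boundary.  Quantum noise is added after the blur: patient motion smears
anatomy, not the per-pixel photon statistics, which is what keeps
high-frequency spectral power alive in blurred regions of real mammograms.

The generator is the self-contained test bed for the whole pipeline: it
emits the same raster/annotation formats the readers consume, together
with exact truth masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .errors import ConfigurationError
from .io import BlurAnnotation, Mammogram, rasterize_annotation, write_annotation, write_mammogram

QUANT_SCALE = 40000.0  # [0,1]-ish signal -> 16-bit integers


@dataclass
class BlurRegion:
    polygon: np.ndarray  # (n, 2) vertices, (x, y) pixel coordinates
    psf_length_px: float
    psf_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.psf_length_px < 0:
            raise ConfigurationError("psf_length_px must be >= 0")


@dataclass
class PhantomConfig:
    """Study conditions for one phantom.

    Defaults emulate the clinical acquisition at test scale: 0.05 mm pitch,
    a 1/f^3 anatomical power law (the accepted exponent range for
    mammographic texture is ~2.5-3.5), and quantum noise at ~1% of the
    full signal.  ``image_px`` of 1,200 keeps a phantom at 6 x 6 cm — large
    enough to carry tens of 1-cm analysis windows; full clinical scale is a
    configuration choice, not a code path.
    """

    image_px: int = 1200
    pixel_spacing_mm: float = 0.05
    texture_beta: float = 3.0
    texture_amp: float = 0.12
    noise_gain: float = 0.01
    base_intensity: float = 0.5
    dome_amp: float = 0.35
    support_row_frac: float = 0.47  # vertical semi-axis / image height
    support_col_frac: float = 0.85  # horizontal semi-axis / image width
    blur_regions: list = field(default_factory=list)
    laterality: str = "L"
    view: str = "CC"
    patient_id: str = "P000"
    source_id: str = "phantom"
    seed: int = 0


@dataclass
class PhantomSample:
    mammogram: Mammogram
    annotation: BlurAnnotation
    truth: dict  # {"support": bool mask, "blur": bool mask, "regions": [...]}


def line_psf(length_px: float, angle_deg: float = 0.0) -> np.ndarray:
    """Unit-sum line kernel of the given length and direction.

    Lengths <= 1 px collapse to the identity (delta) kernel.  The segment
    is supersampled and deposited with bilinear weights, so oblique angles
    keep unit mass exactly.
    """
    if length_px <= 1.0:
        return np.ones((1, 1))
    half = length_px / 2.0
    size = int(np.ceil(length_px)) + 2
    if size % 2 == 0:
        size += 1
    center = size // 2
    kernel = np.zeros((size, size))
    theta = np.deg2rad(angle_deg)
    n_steps = max(int(np.ceil(length_px * 8)), 8)
    ts = np.linspace(-half, half, n_steps)
    rr = center + ts * np.sin(theta)
    cc = center + ts * np.cos(theta)
    r0 = np.floor(rr).astype(int)
    c0 = np.floor(cc).astype(int)
    fr = rr - r0
    fc = cc - c0
    for dr, dc, wgt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        np.add.at(kernel, (r0 + dr, c0 + dc), wgt)
    return kernel / kernel.sum()


def power_law_texture(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with power spectrum 1/f^beta."""
    white = rng.standard_normal((n, n))
    f = np.fft.fftfreq(n)
    r = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    amp = np.zeros_like(r)
    nonzero = r > 0
    amp[nonzero] = r[nonzero] ** (-beta / 2.0)
    fielded = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    fielded -= fielded.mean()
    std = fielded.std()
    return fielded / std if std > 0 else fielded


def breast_support(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """(support mask, normalized elliptical radius) for the configured
    laterality; the chest wall sits on the image edge the breast abuts."""
    n = cfg.image_px
    rows = np.arange(n)[:, None]
    cols = np.arange(n)[None, :]
    a = cfg.support_row_frac * n
    b = cfg.support_col_frac * n
    x = cols if cfg.laterality == "L" else (n - 1 - cols)
    e = np.sqrt(((rows - n / 2.0) / a) ** 2 + (x / b) ** 2)
    return e <= 1.0, e


def generate_phantom(cfg: PhantomConfig) -> PhantomSample:
    """Render one phantom; bit-identical for identical config + seed."""
    n = cfg.image_px
    rng = np.random.default_rng(cfg.seed)
    support, e = breast_support(cfg)

    # anatomy: thickness dome + correlated texture, zero outside the breast
    dome = cfg.base_intensity + cfg.dome_amp * np.sqrt(np.clip(1.0 - e**2, 0.0, None))
    texture = power_law_texture(n, cfg.texture_beta, rng)
    signal = np.where(support, dome + cfg.texture_amp * texture, 0.0)
    noise_field = rng.standard_normal((n, n))  # drawn before blur: independent of it

    blur_mask_total = np.zeros((n, n), dtype=bool)
    polygons = []
    for region in cfg.blur_regions:
        region = region if isinstance(region, BlurRegion) else BlurRegion(*region)
        poly_mask = rasterize_annotation(BlurAnnotation([region.polygon]), (n, n))
        if np.any(poly_mask & ~support):
            raise ConfigurationError("blur polygon extends outside the breast support")
        kernel = line_psf(region.psf_length_px, region.psf_angle_deg)
        if kernel.size > 1:
            blurred = fftconvolve(signal, kernel, mode="same")
            alpha = gaussian_filter(poly_mask.astype(float), sigma=4.0)
            signal = signal * (1.0 - alpha) + blurred * alpha
        blur_mask_total |= poly_mask
        polygons.append(region.polygon)

    noisy = signal + cfg.noise_gain * np.sqrt(np.clip(signal, 0.0, None)) * noise_field
    pixels = np.clip(np.rint(noisy * QUANT_SCALE), 0, 65535).astype(np.uint16)

    mammogram = Mammogram(
        pixels=pixels,
        pixel_spacing_mm=cfg.pixel_spacing_mm,
        laterality=cfg.laterality,
        view=cfg.view,
        patient_id=cfg.patient_id,
        source_id=cfg.source_id,
    )
    annotation = BlurAnnotation(polygons=polygons, reader_id="truth")
    truth = {
        "support": support,
        "blur": blur_mask_total,
        "regions": list(cfg.blur_regions),
    }
    return PhantomSample(mammogram=mammogram, annotation=annotation, truth=truth)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

_BLOCK_SHAPES = ((3, 4), (4, 3), (3, 5), (5, 3), (4, 4))


def _place_blur_polygon(
    cfg: PhantomConfig,
    rng: np.random.Generator,
    window_px: int,
    margin_px: int,
) -> np.ndarray | None:
    """Random lattice-aligned rectangle fully inside the eroded support.

    Aligning to the analysis lattice makes the truth directly comparable to
    the windowed decision; the block sizes keep annotated regions above the
    ten-window minimum the image-level rule demands.
    """
    support, e = breast_support(cfg)
    n = cfg.image_px
    shapes = list(_BLOCK_SHAPES)
    rng.shuffle(shapes)
    for k_r, k_c in shapes:
        bh, bw = k_r * window_px, k_c * window_px
        max_i = (n - bh) // window_px
        max_j = (n - bw) // window_px
        if max_i < 0 or max_j < 0:
            continue
        candidates = [(i, j) for i in range(max_i + 1) for j in range(max_j + 1)]
        rng.shuffle(candidates)
        for i, j in candidates:
            r0, c0 = i * window_px, j * window_px
            block = support[r0 : r0 + bh, c0 : c0 + bw]
            if block.all() and _deep_inside(e[r0 : r0 + bh, c0 : c0 + bw], margin_px, cfg):
                return np.array(
                    [[c0, r0], [c0 + bw, r0], [c0 + bw, r0 + bh], [c0, r0 + bh]], dtype=float
                )
    return None


def _deep_inside(e_block: np.ndarray, margin_px: int, cfg: PhantomConfig) -> bool:
    # keep the whole block at least `margin_px` inside the support boundary
    # (approximated through the normalized elliptical radius)
    shrink = margin_px / (min(cfg.support_row_frac, cfg.support_col_frac) * cfg.image_px)
    return bool((e_block <= 1.0 - shrink).all())


def generate_cohort(
    n_patients: int,
    blur_prevalence: float = 0.5,
    template: PhantomConfig | None = None,
    seed: int = 0,
    window_px: int = 200,
    psf_length_range: tuple[float, float] = (6.0, 12.0),
    margin_px: int = 60,
) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Simulate a screening cohort: 4 views (L/R x CC/MLO) per patient.

    Each view independently receives one randomly placed blur polygon with
    probability ``blur_prevalence``; PSF length is drawn uniformly from
    ``psf_length_range`` (0.3-0.6 mm of motion at 0.05 mm pitch — the
    amplitude range that degrades mammograms visibly).  Returns the samples
    and a ground-truth manifest.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    if not 0.0 <= blur_prevalence <= 1.0:
        raise ConfigurationError("blur_prevalence must lie in [0, 1]")
    template = template or PhantomConfig()
    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    rows = []
    for p in range(n_patients):
        patient_id = f"P{p:04d}"
        for laterality in ("L", "R"):
            for view in ("CC", "MLO"):
                source_id = f"{patient_id}_{laterality}{view}"
                phantom_seed = int(rng.integers(0, 2**31))
                is_blurred = bool(rng.random() < blur_prevalence)
                regions = []
                psf_len = np.nan
                psf_ang = np.nan
                cfg = replace(
                    template,
                    laterality=laterality,
                    view=view,
                    patient_id=patient_id,
                    source_id=source_id,
                    seed=phantom_seed,
                    blur_regions=[],
                )
                if is_blurred:
                    poly = _place_blur_polygon(cfg, rng, window_px, margin_px)
                    if poly is None:
                        raise ConfigurationError(
                            "no admissible blur placement; enlarge image_px or support"
                        )
                    psf_len = float(rng.uniform(*psf_length_range))
                    psf_ang = float(rng.uniform(0.0, 180.0))
                    regions = [BlurRegion(poly, psf_len, psf_ang)]
                cfg = replace(cfg, blur_regions=regions)
                samples.append(generate_phantom(cfg))
                rows.append(
                    {
                        "patient_id": patient_id,
                        "source_id": source_id,
                        "laterality": laterality,
                        "view": view,
                        "blurred": is_blurred,
                        "psf_length_px": psf_len,
                        "psf_angle_deg": psf_ang,
                        "seed": phantom_seed,
                    }
                )
    return samples, pd.DataFrame(rows)


def write_cohort(
    samples: list[PhantomSample], manifest: pd.DataFrame, directory: str | Path
) -> Path:
    """Persist a cohort in the formats the readers consume: 16-bit PNG +
    YAML sidecar per phantom, GeoJSON per annotated phantom, manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sample in samples:
        m = sample.mammogram
        write_mammogram(m, directory / f"{m.source_id}.png")
        if len(sample.annotation):
            write_annotation(sample.annotation, directory / f"{m.source_id}.geojson")
    manifest.to_csv(directory / "manifest.csv", index=False)
    return directory
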