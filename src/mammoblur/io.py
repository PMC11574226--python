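"""Reading and writing of images, annotations, masks and probability maps.

Mammograms come either as DICOM files (pixel spacing, laterality and view
read from tags) or as 16-bit PNG/TIFF rasters with a YAML sidecar carrying
the same metadata.  Blur annotations are GeoJSON polygon collections in
image pixel coordinates.

Coordinate convention: 0-based, row-major, origin at the top-left corner.
Pixel ``(r, c)`` covers the half-open square ``[r, r+1) x [c, c+1)`` and its
center sits at ``(r + 0.5, c + 0.5)``.  Polygon vertices are stored GeoJSON
style as ``(x, y) = (col, row)`` pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from matplotlib.path import Path as MplPath
from PIL import Image

from .errors import FormatError, MetadataError, ShapeError

logger = logging.getLogger(__name__)

LATERALITIES = ("L", "R")
VIEWS = ("CC", "MLO")

_DICOM_SUFFIXES = {".dcm", ".dicom", ".dic"}
_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class Mammogram:
    """A single-view mammogram raster plus the acquisition metadata the
    pipeline needs.

    ``pixels`` follow a monotone-increasing photometric convention: higher
    value means more signal (MONOCHROME1 inputs are inverted on read).
    """

    pixels: np.ndarray
    pixel_spacing_mm: float
    laterality: str
    view: str
    patient_id: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise FormatError(
                f"pixel raster must be 2-D with >=2 rows/cols, got shape {self.pixels.shape}"
            )
        if not self.pixel_spacing_mm > 0:
            raise MetadataError(f"pixel_spacing_mm must be positive, got {self.pixel_spacing_mm}")
        if self.laterality not in LATERALITIES:
            raise MetadataError(f"laterality must be one of {LATERALITIES}, got {self.laterality!r}")
        if self.view not in VIEWS:
            raise MetadataError(f"view must be one of {VIEWS}, got {self.view!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def replace_pixels(self, pixels: np.ndarray) -> "Mammogram":
        return Mammogram(
            pixels=pixels,
            pixel_spacing_mm=self.pixel_spacing_mm,
            laterality=self.laterality,
            view=self.view,
            patient_id=self.patient_id,
            source_id=self.source_id,
        )


@dataclass
class BlurAnnotation:
    """Reader-drawn blurred regions as closed polygons in pixel coordinates.

    Each polygon is an ``(n, 2)`` float array of ``(x, y)`` vertices with
    ``n >= 3``; the closing edge back to the first vertex is implicit.
    """

    polygons: list[np.ndarray] = field(default_factory=list)
    reader_id: str = ""

    def __post_init__(self) -> None:
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise FormatError(f"polygon must be (n>=3, 2), got shape {p.shape}")

    def __len__(self) -> int:
        return len(self.polygons)

    def area_cm2(self, pixel_spacing_mm: float) -> float:
        """Total annotated area in cm^2 (shoelace formula, per polygon)."""
        px_area_mm2 = pixel_spacing_mm**2
        total_px = sum(_shoelace_area(p) for p in self.polygons)
        return total_px * px_area_mm2 / 100.0


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


# ---------------------------------------------------------------------------
# mammogram reading / writing
# ---------------------------------------------------------------------------

def read_mammogram(
    path: str | Path,
    *,
    pixel_spacing_mm: float | None = None,
    laterality: str | None = None,
    view: str | None = None,
    patient_id: str | None = None,
) -> Mammogram:
    """Read a mammogram from DICOM or PNG/TIFF-plus-sidecar.

    Keyword overrides take precedence over file tags; a value present in
    neither place raises :class:`MetadataError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _DICOM_SUFFIXES:
        return _read_dicom(path, pixel_spacing_mm, laterality, view, patient_id)
    if path.suffix.lower() in _RASTER_SUFFIXES:
        return _read_raster(path, pixel_spacing_mm, laterality, view, patient_id)
    raise FormatError(f"unsupported image format: {path.suffix!r}")


def _read_dicom(path, spacing, laterality, view, patient_id) -> Mammogram:
    import pydicom

    ds = pydicom.dcmread(path, force=True)
    try:
        pixels = ds.pixel_array
    except Exception as exc:  # pragma: no cover - corrupt input
        raise FormatError(f"cannot decode pixel data in {path}: {exc}") from exc
    if pixels.ndim != 2:
        raise FormatError(f"expected single-frame grayscale DICOM, got shape {pixels.shape}")

    photometric = getattr(ds, "PhotometricInterpretation", "MONOCHROME2")
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise FormatError(f"non-grayscale photometric interpretation {photometric!r}")
    if photometric == "MONOCHROME1":
        # invert so that higher stored value always means more signal
        bits = int(getattr(ds, "BitsStored", 0))
        vmax = (1 << bits) - 1 if bits else int(pixels.max())
        pixels = vmax - pixels

    if spacing is None:
        tag = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
        if tag is None:
            raise MetadataError(f"{path}: no Pixel Spacing / Imager Pixel Spacing tag and no override")
        spacing = float(tag[0])
    if laterality is None:
        laterality = str(getattr(ds, "ImageLaterality", "") or getattr(ds, "Laterality", ""))
        if laterality not in LATERALITIES:
            raise MetadataError(f"{path}: missing/ambiguous Image Laterality and no override")
    if view is None:
        view = str(getattr(ds, "ViewPosition", ""))
        if view not in VIEWS:
            raise MetadataError(f"{path}: missing/ambiguous View Position and no override")
    if patient_id is None:
        patient_id = str(getattr(ds, "PatientID", ""))

    return Mammogram(
        pixels=pixels,
        pixel_spacing_mm=spacing,
        laterality=laterality,
        view=view,
        patient_id=patient_id,
        source_id=path.stem,
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _read_raster(path, spacing, laterality, view, patient_id) -> Mammogram:
    img = Image.open(path)
    if img.mode in ("I;16", "I;16B", "I"):
        pixels = np.asarray(img, dtype=np.uint16 if "16" in img.mode else np.int32)
    elif img.mode == "L":
        pixels = np.asarray(img, dtype=np.uint8)
    elif img.mode == "F":
        pixels = np.asarray(img, dtype=np.float32)
    else:
        raise FormatError(f"{path}: non-grayscale image mode {img.mode!r}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}

    spacing = spacing if spacing is not None else meta.get("pixel_spacing_mm")
    laterality = laterality if laterality is not None else meta.get("laterality")
    view = view if view is not None else meta.get("view")
    patient_id = patient_id if patient_id is not None else meta.get("patient_id", "")
    if spacing is None:
        raise MetadataError(f"{path}: pixel spacing not in sidecar and no override given")
    if laterality is None or view is None:
        raise MetadataError(f"{path}: laterality/view not in sidecar and no override given")
    return Mammogram(
        pixels=pixels,
        pixel_spacing_mm=float(spacing),
        laterality=str(laterality),
        view=str(view),
        patient_id=str(patient_id),
        source_id=str(meta.get("source_id", path.stem)),
    )


def write_mammogram(m: Mammogram, path: str | Path) -> Path:
    """Write a mammogram as 16-bit PNG (or TIFF) plus a YAML sidecar.

    Integer rasters round-trip bit-identically through PNG.
    """
    path = Path(path)
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise FormatError(f"write_mammogram supports PNG/TIFF, got {path.suffix!r}")
    pixels = m.pixels
    if not np.issubdtype(pixels.dtype, np.integer):
        raise FormatError("write_mammogram requires an integer raster; quantize first")
    if pixels.min() < 0 or pixels.max() > 65535:
        raise FormatError("raster values outside the 16-bit range")
    Image.fromarray(pixels.astype(np.uint16)).save(path)
    meta = {
        "pixel_spacing_mm": float(m.pixel_spacing_mm),
        "laterality": m.laterality,
        "view": m.view,
        "patient_id": m.patient_id,
        "source_id": m.source_id or path.stem,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, image_shape: tuple[int, int]) -> BlurAnnotation:
    """Read a GeoJSON polygon annotation and clip it to the image bounds.

    Degenerate loops (fewer than 3 distinct vertices) are dropped with a
    logged warning rather than raising.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse annotation file {path}: {exc}") from exc

    reader_id = ""
    raw_polys: list[list] = []
    if doc.get("type") == "FeatureCollection":
        for feat in doc.get("features", []):
            geom = feat.get("geometry") or {}
            reader_id = feat.get("properties", {}).get("reader_id", reader_id)
            raw_polys.extend(_geometry_rings(geom))
    else:
        raw_polys.extend(_geometry_rings(doc))

    polygons = []
    for ring in raw_polys:
        poly = np.asarray(ring, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2:
            raise FormatError(f"{path}: malformed polygon ring of shape {poly.shape}")
        if len(poly) > 1 and np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]  # drop explicit GeoJSON closing vertex
        if len(poly) < 3:
            logger.warning("%s: dropping degenerate polygon with %d vertices", path, len(poly))
            continue
        clipped = clip_polygon_to_bounds(poly, image_shape)
        for piece in clipped:
            if len(piece) >= 3:
                polygons.append(piece)
    return BlurAnnotation(polygons=polygons, reader_id=reader_id)


def _geometry_rings(geom: dict) -> list[list]:
    gtype = geom.get("type")
    coords = geom.get("coordinates", [])
    if gtype == "Polygon":
        return [coords[0]] if coords else []
    if gtype == "MultiPolygon":
        return [poly[0] for poly in coords if poly]
    if gtype is None and not coords:
        return []
    raise FormatError(f"unsupported geometry type {gtype!r}")


def write_annotation(ann: BlurAnnotation, path: str | Path) -> Path:
    """Write an annotation as a GeoJSON FeatureCollection."""
    features = []
    for poly in ann.polygons:
        ring = [[float(x), float(y)] for x, y in poly] + [[float(poly[0, 0]), float(poly[0, 1])]]
        features.append(
            {
                "type": "Feature",
                "properties": {"reader_id": ann.reader_id},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


def clip_polygon_to_bounds(poly: np.ndarray, image_shape: tuple[int, int]) -> list[np.ndarray]:
    """Clip a polygon to ``[0, W] x [0, H]``; may split into several pieces."""
    from shapely.geometry import MultiPolygon, Polygon, box

    h, w = image_shape
    shp = Polygon(poly)
    if not shp.is_valid:
        shp = shp.buffer(0)
    clipped = shp.intersection(box(0.0, 0.0, float(w), float(h)))
    pieces: list[np.ndarray] = []
    if clipped.is_empty:
        return pieces
    geoms = clipped.geoms if isinstance(clipped, MultiPolygon) else [clipped]
    for g in geoms:
        if g.geom_type != "Polygon" or g.area == 0:
            continue
        coords = np.asarray(g.exterior.coords[:-1], dtype=float)
        if len(coords) >= 3:
            pieces.append(coords)
    return pieces


def rasterize_annotation(ann: BlurAnnotation, image_shape: tuple[int, int]) -> np.ndarray:
    """Render polygons to a boolean mask.

    A pixel is set iff its center ``(r + 0.5, c + 0.5)`` lies inside at
    least one polygon (even-odd rule).
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if h <= 0 or w <= 0:
        raise ShapeError(f"image_shape must be positive, got {image_shape}")
    mask = np.zeros((h, w), dtype=bool)
    for poly in ann.polygons:
        # work on the bounding box only; polygons are usually local
        xmin = max(int(np.floor(poly[:, 0].min() - 1)), 0)
        xmax = min(int(np.ceil(poly[:, 0].max() + 1)), w)
        ymin = max(int(np.floor(poly[:, 1].min() - 1)), 0)
        ymax = min(int(np.ceil(poly[:, 1].max() + 1)), h)
        if xmin >= xmax or ymin >= ymax:
            continue
        cols = np.arange(xmin, xmax) + 0.5
        rows = np.arange(ymin, ymax) + 0.5
        cc, rr = np.meshgrid(cols, rows)
        pts = np.column_stack([cc.ravel(), rr.ravel()])
        ring = np.vstack([poly, poly[:1]])  # closed=True consumes the last vertex
        inside = MplPath(ring, closed=True).contains_points(pts)
        mask[ymin:ymax, xmin:xmax] |= inside.reshape(ymax - ymin, xmax - xmin)
    return mask


# ---------------------------------------------------------------------------
# binary masks (pectoralis / truth masks)
# ---------------------------------------------------------------------------

def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask from PNG (nonzero = true) or NPZ (key ``mask``)."""
    path = Path(path)
    if path.suffix.lower() == ".npz":
        with np.load(path) as data:
            return data["mask"].astype(bool)
    img = Image.open(path)
    return np.asarray(img) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".npz":
        np.savez_compressed(path, mask=mask.astype(bool))
    else:
        Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(path)
    return path
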