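"""Image-level blur verdict from a per-window probability map.

The decision cascade mirrors clinical retake reasoning: individual windows
below a probability threshold (0.45) are discarded; surviving windows must
form a connected region of at least ten windows (tiny patches lack
diagnostic relevance); and the region's mean probability must reach 0.65.
A mammogram is called blurred iff at least one region survives all three
stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ShapeError


@dataclass
class DecisionConfig:
    window_threshold: float = 0.45
    min_component_windows: int = 10
    mean_prob_threshold: float = 0.65
    connectivity: int = 8  # lattice adjacency: 4 or 8

    def __post_init__(self) -> None:
        for name in ("window_threshold", "mean_prob_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.min_component_windows < 1:
            raise ConfigurationError("min_component_windows must be >= 1")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")


@dataclass
class ProbabilityMap:
    """Lattice of per-window blur probabilities.

    ``grid[i, j]`` is the probability for the window with pixel origin
    ``origin + (i * stride, j * stride)``; NaN marks windows that were not
    analyzed (insufficient mask coverage).
    """

    grid: np.ndarray
    window_px: int
    stride_px: int
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ShapeError("probability grid must be 2-D")
        finite = self.grid[np.isfinite(self.grid)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ShapeError("probabilities must lie in [0, 1]")
        if self.window_px < 1 or self.stride_px < 1:
            raise ShapeError("window_px and stride_px must be positive")

    def cell_origin(self, i: int, j: int) -> tuple[int, int]:
        return (self.origin[0] + i * self.stride_px, self.origin[1] + j * self.stride_px)

    def canvas_shape(self) -> tuple[int, int]:
        h = self.origin[0] + (self.grid.shape[0] - 1) * self.stride_px + self.window_px
        w = self.origin[1] + (self.grid.shape[1] - 1) * self.stride_px + self.window_px
        return (h, w)

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "origin": list(self.origin),
            "window_px": self.window_px,
            "stride_px": self.stride_px,
            "grid": [[None if not np.isfinite(v) else float(v) for v in row] for row in self.grid],
        }
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ProbabilityMap":
        with open(Path(path)) as fh:
            doc = json.load(fh)
        grid = np.array(
            [[np.nan if v is None else v for v in row] for row in doc["grid"]], dtype=float
        )
        return cls(
            grid=grid,
            window_px=doc["window_px"],
            stride_px=doc["stride_px"],
            origin=tuple(doc["origin"]),
        )


@dataclass
class RetainedComponent:
    cells: list  # [(i, j), ...] lattice coordinates
    mean_probability: float


@dataclass
class ImageVerdict:
    label: str  # "blurred" | "sharp"
    retained_components: list = field(default_factory=list)
    blur_pixel_mask: np.ndarray | None = None

    @property
    def is_blurred(self) -> bool:
        return self.label == "blurred"


def decide(pmap: ProbabilityMap, cfg: DecisionConfig | None = None) -> ImageVerdict:
    """Apply the three-stage cascade to a probability map.

    Raising any cell's probability can only help a component survive, so
    the verdict is monotone in the map.
    """
    cfg = cfg or DecisionConfig()
    grid = pmap.grid
    if grid.size == 0:
        raise ShapeError("empty probability map")
    surviving = np.isfinite(grid) & (grid >= cfg.window_threshold)
    structure = ndimage.generate_binary_structure(2, 2 if cfg.connectivity == 8 else 1)
    labels, n = ndimage.label(surviving, structure=structure)
    retained = []
    for comp in range(1, n + 1):
        cells = np.argwhere(labels == comp)
        if len(cells) < cfg.min_component_windows:
            continue
        # fsum: correctly rounded, order-independent — exact ties between a
        # component mean and the threshold resolve deterministically
        vals = grid[labels == comp]
        mean_p = math.fsum(vals) / len(vals)
        if mean_p < cfg.mean_prob_threshold:
            continue
        retained.append(
            RetainedComponent(cells=[tuple(map(int, c)) for c in cells], mean_probability=mean_p)
        )
    label = "blurred" if retained else "sharp"
    verdict = ImageVerdict(label=label, retained_components=retained)
    verdict.blur_pixel_mask = render_mask(verdict, pmap, pmap.canvas_shape())
    return verdict


def render_mask(
    verdict: ImageVerdict, geometry: ProbabilityMap, image_shape: tuple[int, int]
) -> np.ndarray:
    """Union of the pixel footprints of all retained windows."""
    h, w = image_shape
    canvas_h, canvas_w = geometry.canvas_shape()
    if h < canvas_h or w < canvas_w:
        raise ShapeError(f"image shape {image_shape} smaller than grid canvas {(canvas_h, canvas_w)}")
    mask = np.zeros((h, w), dtype=bool)
    win = geometry.window_px
    for comp in verdict.retained_components:
        for i, j in comp.cells:
            r0, c0 = geometry.cell_origin(i, j)
            mask[r0 : r0 + win, c0 : c0 + win] = True
    return mask


def verdict_to_json(verdict: ImageVerdict, path: str | Path) -> Path:
    doc = {
        "label": verdict.label,
        "components": [
            {"cells": [list(c) for c in comp.cells], "mean_probability": comp.mean_probability}
            for comp in verdict.retained_components
        ],
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path
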