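"""Sliding-window dataset assembly and patient-stratified splitting.

A fixed-size analysis window (200 x 200 px by default, i.e. 1 x 1 cm at
0.05 mm pitch) is slid over each preprocessed mammogram on a stride
lattice.  Windows sufficiently covered by the breast-interior mask get an
nWS spectrum and — when reader polygons are available — a blurred/sharp
label.  Splits and cross-validation folds always keep all images of one
patient together to prevent leakage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import Mammogram
from .nws import NwsConfig, NwsSpectrum, compute_nws

BLURRED, SHARP = "blurred", "sharp"


@dataclass
class WindowGridConfig:
    window_px: int = 200
    stride_px: int | None = None  # None -> non-overlapping lattice (= window_px)
    min_mask_fraction: float = 0.9
    blur_label_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_px < 1:
            raise ConfigurationError("window_px must be positive")
        if self.stride_px is None:
            self.stride_px = self.window_px
        if not 1 <= self.stride_px <= self.window_px:
            raise ConfigurationError("stride_px must satisfy 1 <= stride <= window")
        for name in ("min_mask_fraction", "blur_label_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1]")


@dataclass
class GridWindow:
    """One analysis window: lattice coordinate (i, j) and pixel origin."""

    i: int
    j: int
    r0: int
    c0: int
    size_px: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.r0, self.r0 + self.size_px), slice(self.c0, self.c0 + self.size_px)


@dataclass
class WindowRecord:
    source_id: str
    patient_id: str
    grid_coord: tuple[int, int]
    spectrum: NwsSpectrum
    label: str | None = None


@dataclass
class SplitPlan:
    """Patient-level assignment for the holdout split and CV folds."""

    assignment: dict = field(default_factory=dict)  # patient_id -> "train" | "test"
    folds: dict = field(default_factory=dict)  # patient_id -> fold index (train part only)
    fractions: tuple = (0.8, 0.2)
    k_folds: int = 0
    seed: int = 0

    def patients(self, part: str) -> list[str]:
        return sorted(p for p, a in self.assignment.items() if a == part)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        with open(path) as fh:
            doc = json.load(fh)
        doc["fractions"] = tuple(doc["fractions"])
        return cls(**doc)


def enumerate_windows(
    m: Mammogram, mask: np.ndarray, cfg: WindowGridConfig | None = None
) -> list[GridWindow]:
    """All stride-lattice windows with mask coverage >= min_mask_fraction.

    Lattice coordinates ``(i, j)`` map bijectively to pixel origins
    ``(i * stride, j * stride)``; windows are half-open
    ``[r0, r0+win) x [c0, c0+win)``.
    """
    cfg = cfg or WindowGridConfig()
    h, w = mask.shape
    win, stride = cfg.window_px, cfg.stride_px
    out: list[GridWindow] = []
    if h < win or w < win:
        return out
    # integral image gives O(1) coverage per window
    cum = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=cum[1:, 1:])
    area = win * win
    for i, r0 in enumerate(range(0, h - win + 1, stride)):
        for j, c0 in enumerate(range(0, w - win + 1, stride)):
            covered = (
                cum[r0 + win, c0 + win]
                - cum[r0, c0 + win]
                - cum[r0 + win, c0]
                + cum[r0, c0]
            )
            if covered / area >= cfg.min_mask_fraction:
                out.append(GridWindow(i=i, j=j, r0=r0, c0=c0, size_px=win))
    return out


def label_window(
    window: GridWindow, blur_mask: np.ndarray, cfg: WindowGridConfig | None = None
) -> str:
    """Blurred iff the window's overlap with the blur mask reaches
    ``blur_label_fraction`` of its area."""
    cfg = cfg or WindowGridConfig(window_px=window.size_px)
    frac = float(blur_mask[window.slices].mean())
    return BLURRED if frac >= cfg.blur_label_fraction else SHARP


def extract_window_records(
    m: Mammogram,
    mask: np.ndarray,
    blur_mask: np.ndarray | None = None,
    grid_cfg: WindowGridConfig | None = None,
    nws_cfg: NwsConfig | None = None,
) -> list[WindowRecord]:
    """Spectra (and labels, when a blur mask is given) for every analysis
    window of one preprocessed mammogram."""
    grid_cfg = grid_cfg or WindowGridConfig()
    nws_cfg = nws_cfg or NwsConfig()
    pixels = np.asarray(m.pixels, dtype=np.float64)
    records = []
    for gw in enumerate_windows(m, mask, grid_cfg):
        spec = compute_nws(pixels[gw.slices], m.pixel_spacing_mm, nws_cfg, origin=(gw.r0, gw.c0))
        label = None if blur_mask is None else label_window(gw, blur_mask, grid_cfg)
        records.append(
            WindowRecord(
                source_id=m.source_id,
                patient_id=m.patient_id,
                grid_coord=(gw.i, gw.j),
                spectrum=spec,
                label=label,
            )
        )
    return records


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def make_splits(
    records: list[WindowRecord],
    fractions: tuple[float, float] = (0.8, 0.2),
    k_folds: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Patient-stratified train/test split plus CV folds over the train part.

    Patients are shuffled by the seed, then filled greedily into the train
    part until its record count reaches the target fraction; the train
    patients are dealt into ``k_folds`` folds balancing record counts.
    Deterministic given the seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must sum to 1")
    counts: dict[str, int] = {}
    for rec in records:
        if not rec.patient_id:
            raise ConfigurationError("every record needs a patient_id for stratified splits")
        counts[rec.patient_id] = counts.get(rec.patient_id, 0) + 1
    patients = sorted(counts)
    if k_folds and len(patients) < k_folds:
        raise ConfigurationError(f"{len(patients)} patients < {k_folds} folds")

    rng = np.random.default_rng(seed)
    order = [patients[k] for k in rng.permutation(len(patients))]
    total = sum(counts.values())
    target = fractions[0] * total
    assignment: dict[str, str] = {}
    acc = 0
    for pid in order:
        # add to train while it brings the realized fraction closer to target
        if abs(acc + counts[pid] - target) <= abs(acc - target):
            assignment[pid] = "train"
            acc += counts[pid]
        else:
            assignment[pid] = "test"
    if fractions[1] > 0 and "test" not in assignment.values() and len(order) > 1:
        assignment[order[-1]] = "test"
    if fractions[0] > 0 and "train" not in assignment.values():
        assignment[order[0]] = "train"

    folds: dict[str, int] = {}
    if k_folds:
        train_patients = [p for p in order if assignment[p] == "train"]
        if len(train_patients) < k_folds:
            raise ConfigurationError("too few train patients for the requested folds")
        # largest-first greedy balance of record counts across folds
        fold_sizes = [0] * k_folds
        for pid in sorted(train_patients, key=lambda p: (-counts[p], order.index(p))):
            f = int(np.argmin(fold_sizes))
            folds[pid] = f
            fold_sizes[f] += counts[pid]
    return SplitPlan(
        assignment=assignment, folds=folds, fractions=tuple(fractions), k_folds=k_folds, seed=seed
    )


def select_records(records: list[WindowRecord], plan: SplitPlan, part: str) -> list[WindowRecord]:
    if part in ("train", "test"):
        keep = {p for p, a in plan.assignment.items() if a == part}
    else:
        raise ConfigurationError(f"unknown part {part!r}")
    return [r for r in records if r.patient_id in keep]


def class_weights(records_or_counts) -> dict[str, float]:
    """Inverse-frequency class weights, normalized to mean 1.

    Accepts either labelled records or a ``{label: count}`` mapping; used to
    weight the cross-entropy loss against the heavy sharp/blurred imbalance.
    """
    if isinstance(records_or_counts, dict):
        counts = dict(records_or_counts)
    else:
        counts = {}
        for rec in records_or_counts:
            if rec.label is not None:
                counts[rec.label] = counts.get(rec.label, 0) + 1
    if len(counts) < 2 or any(v <= 0 for v in counts.values()):
        raise ConfigurationError(f"class_weights needs two populated classes, got {counts}")
    inv = {k: 1.0 / v for k, v in counts.items()}
    mean_inv = sum(inv.values()) / len(inv)
    return {k: v / mean_inv for k, v in inv.items()}


# ---------------------------------------------------------------------------
# spectra batch files
# ---------------------------------------------------------------------------

def records_to_frame(records: list[WindowRecord]) -> pd.DataFrame:
    """Tabulate records: metadata columns + one ``v@<freq>`` column per bin."""
    if not records:
        return pd.DataFrame()
    freqs = records[0].spectrum.freqs_mm
    rows = []
    for rec in records:
        if not np.array_equal(rec.spectrum.freqs_mm, freqs):
            raise ConfigurationError("all spectra must share one frequency axis")
        row = {
            "source_id": rec.source_id,
            "patient_id": rec.patient_id,
            "grid_i": rec.grid_coord[0],
            "grid_j": rec.grid_coord[1],
            "label": rec.label,
        }
        row.update({f"v@{f:.6g}": v for f, v in zip(freqs, rec.spectrum.values)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[WindowRecord]:
    value_cols = [c for c in df.columns if c.startswith("v@")]
    freqs = np.array([float(c[2:]) for c in value_cols])
    records = []
    for _, row in df.iterrows():
        spec = NwsSpectrum(freqs_mm=freqs, values=row[value_cols].to_numpy(dtype=float))
        label = row["label"] if isinstance(row["label"], str) else None
        records.append(
            WindowRecord(
                source_id=str(row["source_id"]),
                patient_id=str(row["patient_id"]),
                grid_coord=(int(row["grid_i"]), int(row["grid_j"])),
                spectrum=spec,
                label=label,
            )
        )
    return records


def save_spectra(records: list[WindowRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def load_spectra(path: str | Path) -> list[WindowRecord]:
    return frame_to_records(pd.read_csv(Path(path)))
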