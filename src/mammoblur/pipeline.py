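"""End-to-end orchestration: image -> spectra -> probabilities -> verdict.

Thin glue over the individual modules, shared by the CLI, the tests and
the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dataset as ds
from .classifier import ClassifierConfig, TrainedModel, as_matrix, build_model, train
from .decision import DecisionConfig, ImageVerdict, ProbabilityMap, decide
from .evaluation import auroc, image_level_confusion
from .io import BlurAnnotation, Mammogram, rasterize_annotation
from .nws import NwsConfig
from .preprocess import AnalysisMask, PreprocessConfig, pad_to_canvas, preprocess
from .synthetic import PhantomConfig, PhantomSample, generate_cohort


@dataclass
class PipelineConfig:
    """Aggregated configuration for the full pipeline; round-trips
    losslessly through YAML."""

    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    window: ds.WindowGridConfig = field(default_factory=ds.WindowGridConfig)
    nws: NwsConfig = field(default_factory=NwsConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    evaluation: "EvalConfig" = None  # type: ignore[assignment]
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.evaluation is None:
            from .evaluation import EvalConfig

            self.evaluation = EvalConfig()

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        from .evaluation import EvalConfig

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            preprocessing=PreprocessConfig(**doc["preprocessing"]),
            window=ds.WindowGridConfig(**doc["window"]),
            nws=NwsConfig(**doc["nws"]),
            classifier=ClassifierConfig(**doc["classifier"]),
            decision=DecisionConfig(**doc["decision"]),
            evaluation=EvalConfig(**doc["evaluation"]),
            random_seed=doc["random_seed"],
        )


def rasterize_on_canvas(
    ann: BlurAnnotation, m: Mammogram, cfg: PreprocessConfig
) -> np.ndarray:
    """Rasterize an annotation drawn on the original raster and pad the
    mask onto the analysis canvas alongside the image."""
    mask = rasterize_annotation(ann, m.shape)
    carrier = Mammogram(
        pixels=mask.astype(np.uint8),
        pixel_spacing_mm=m.pixel_spacing_mm,
        laterality=m.laterality,
        view=m.view,
    )
    return pad_to_canvas(carrier, cfg).pixels.astype(bool)


def extract_labelled_records(
    m: Mammogram,
    annotation: BlurAnnotation | None,
    cfg: PipelineConfig,
    pectoralis_mask: np.ndarray | None = None,
) -> tuple[list[ds.WindowRecord], Mammogram, AnalysisMask]:
    """Preprocess one mammogram and extract (optionally labelled) window
    spectra."""
    blur_mask = None
    if annotation is not None:
        blur_mask = rasterize_on_canvas(annotation, m, cfg.preprocessing)
    normalized, mask = preprocess(m, cfg.preprocessing, pectoralis_mask)
    records = ds.extract_window_records(
        normalized, mask.mask, blur_mask, cfg.window, cfg.nws
    )
    return records, normalized, mask


def predict_probability_map(
    model: TrainedModel,
    m: Mammogram,
    cfg: PipelineConfig,
    pectoralis_mask: np.ndarray | None = None,
) -> tuple[ProbabilityMap, ImageVerdict]:
    """Probability map + image verdict for one raw mammogram."""
    normalized, mask = preprocess(m, cfg.preprocessing, pectoralis_mask)
    return predict_on_preprocessed(model, normalized, mask.mask, cfg)


def predict_on_preprocessed(
    model: TrainedModel,
    normalized: Mammogram,
    mask: np.ndarray,
    cfg: PipelineConfig,
    records: list[ds.WindowRecord] | None = None,
) -> tuple[ProbabilityMap, ImageVerdict]:
    if records is None:
        records = ds.extract_window_records(normalized, mask, None, cfg.window, cfg.nws)
    win, stride = cfg.window.window_px, cfg.window.stride_px
    h, w = mask.shape
    n_i = max((h - win) // stride + 1, 0)
    n_j = max((w - win) // stride + 1, 0)
    grid = np.full((n_i, n_j), np.nan)
    if records:
        probs = model.predict_proba(records)
        for rec, p in zip(records, probs):
            grid[rec.grid_coord] = p
    pmap = ProbabilityMap(grid=grid, window_px=win, stride_px=stride)
    verdict = decide(pmap, cfg.decision)
    return pmap, verdict


# ---------------------------------------------------------------------------
# synthetic end-to-end experiment
# ---------------------------------------------------------------------------

def cohort_records(
    samples: list[PhantomSample], cfg: PipelineConfig
) -> list[ds.WindowRecord]:
    records = []
    for sample in samples:
        # cohort phantoms are fully annotated: no polygons means sharp
        recs, _, _ = extract_labelled_records(sample.mammogram, sample.annotation, cfg)
        records.extend(recs)
    return records


def train_on_cohort(
    samples: list[PhantomSample],
    cfg: PipelineConfig,
    val_fraction: float = 0.2,
) -> tuple[TrainedModel, list[ds.WindowRecord]]:
    """Extract labelled windows from a cohort, split patient-stratified
    into train/validation, and fit the classifier."""
    records = cohort_records(samples, cfg)
    plan = ds.make_splits(
        records, fractions=(1.0 - val_fraction, val_fraction), k_folds=0, seed=cfg.random_seed
    )
    tr = ds.select_records(records, plan, "train")
    va = ds.select_records(records, plan, "test")
    weights = ds.class_weights(tr)
    model = build_model(cfg.classifier, freqs_mm=tr[0].spectrum.freqs_mm)
    train(model, tr, va, weights, cfg.classifier)
    return model, records


def evaluate_on_cohort(
    model: TrainedModel,
    samples: list[PhantomSample],
    manifest,
    cfg: PipelineConfig,
) -> dict:
    """Window-level AUROC and image-level confusion on a held-out cohort."""
    truth_by_source = dict(zip(manifest["source_id"], manifest["blurred"]))
    labelled: list[ds.WindowRecord] = []
    verdicts, truths = [], []
    for sample in samples:
        recs, normalized, mask = extract_labelled_records(sample.mammogram, sample.annotation, cfg)
        labelled.extend(r for r in recs if r.label is not None)
        _, verdict = predict_on_preprocessed(model, normalized, mask.mask, cfg, records=recs)
        verdicts.append(verdict.label)
        truths.append("blurred" if truth_by_source[sample.mammogram.source_id] else "sharp")
    scores = model.predict_proba(labelled)
    y = np.array([1 if r.label == ds.BLURRED else 0 for r in labelled])
    window_auroc = auroc(scores, y)
    cm = image_level_confusion(verdicts, truths)
    return {
        "window_auroc": float(window_auroc),
        "image_confusion": cm,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "n_windows": len(labelled),
        "n_images": len(samples),
        "scores": scores,
        "window_labels": y,
    }


def run_synthetic_experiment(
    seed: int = 0,
    n_train_patients: int = 25,
    n_test_patients: int = 10,
    blur_prevalence: float = 0.5,
    cfg: PipelineConfig | None = None,
    template: PhantomConfig | None = None,
) -> dict:
    """Train on one simulated cohort, evaluate on an independent one.

    This is the package's stand-in for the clinical study: the cohorts are
    disjoint by construction (separate generator seeds and patient
    namespaces), the classifier trains with the default hyperparameters,
    and the default decision cascade produces image verdicts.
    """
    cfg = cfg or PipelineConfig()
    cfg.random_seed = seed
    cfg.classifier.seed = seed
    # 1,600 px (8 cm at 0.05 mm pitch) is the smallest lattice-aligned canvas
    # on which a ten-window blurred region fits comfortably inside the breast
    # support, so the image-level decision rule is actually exercisable
    template = template or PhantomConfig(image_px=1600)
    if cfg.preprocessing.canvas_size_px is None:
        cfg.preprocessing = PreprocessConfig(
            canvas_size_px=template.image_px,
            skin_margin_mm=cfg.preprocessing.skin_margin_mm,
            threshold_method=cfg.preprocessing.threshold_method,
            fixed_threshold=cfg.preprocessing.fixed_threshold,
        )
    train_samples, train_manifest = generate_cohort(
        n_train_patients,
        blur_prevalence,
        template,
        seed=seed,
        window_px=cfg.window.window_px,
    )
    test_samples, test_manifest = generate_cohort(
        n_test_patients,
        blur_prevalence,
        template,
        seed=seed + 1_000_003,
        window_px=cfg.window.window_px,
    )
    # separate patient namespaces so the two cohorts can never collide
    for sample in test_samples:
        sample.mammogram.patient_id = "T" + sample.mammogram.patient_id
        sample.mammogram.source_id = "T" + sample.mammogram.source_id
    test_manifest = test_manifest.assign(
        patient_id="T" + test_manifest["patient_id"],
        source_id="T" + test_manifest["source_id"],
    )
    model, _ = train_on_cohort(train_samples, cfg)
    metrics = evaluate_on_cohort(model, test_samples, test_manifest, cfg)
    metrics["model"] = model
    metrics["train_manifest"] = train_manifest
    metrics["test_manifest"] = test_manifest
    return metrics
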