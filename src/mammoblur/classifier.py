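"""Compact 1-D convolutional classifier of nWS spectra.

Architecture: a single 1-D convolution (128 filters, kernel 3, stride 1)
over the spectrum, batch normalization, ReLU, dropout (0.3), flatten and a
dense layer to 2 logits with softmax — i.e. the smallest network that maps
a radial spectrum to a blurred-region probability.  Training minimizes
class-weighted cross-entropy with Adam (lr 1e-5, batch 50) and early stops
on validation loss.

The network is implemented directly on numpy: at this parameter count
(~25k weights for a 100-bin spectrum) vectorized CPU linear algebra trains
in seconds, and a self-contained implementation keeps initialization,
batching and dropout fully deterministic under a single seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import WindowRecord, class_weights as _class_weights, make_splits
from .errors import ConfigurationError, IntegrityError, ShapeError
from .nws import NwsSpectrum

_EPS = 1e-5  # batch-norm variance floor
_LABEL_TO_INT = {"sharp": 0, "blurred": 1}


@dataclass
class ClassifierConfig:
    n_filters: int = 128
    kernel: int = 3
    stride: int = 1
    dropout: float = 0.3
    learning_rate: float = 1e-5
    batch_size: int = 50
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_filters", "kernel", "stride", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")


class TrainedModel:
    """Architecture, learned parameters and the frequency axis they expect.

    The input length and frequency axis are fixed at build time; prediction
    refuses spectra on a different axis.
    """

    def __init__(self, cfg: ClassifierConfig, input_len: int, freqs_mm: np.ndarray | None = None):
        if input_len < cfg.kernel:
            raise ConfigurationError(f"input_len {input_len} < kernel {cfg.kernel}")
        self.cfg = cfg
        self.input_len = int(input_len)
        self.freqs_mm = None if freqs_mm is None else np.asarray(freqs_mm, dtype=float)
        self.conv_len = (input_len - cfg.kernel) // cfg.stride + 1
        self.metadata: dict = {"seed": cfg.seed, "epochs_run": 0, "final_losses": {}}
        self.training_log: list[dict] = []
        self._init_params(np.random.default_rng(cfg.seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        f, k = self.cfg.n_filters, self.cfg.kernel
        d = f * self.conv_len
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / k), size=(f, k)),
            "b1": np.zeros(f),
            "gamma": np.ones(f),
            "beta": np.zeros(f),
            "W2": rng.normal(0.0, np.sqrt(2.0 / (d + 2)), size=(d, 2)),
            "b2": np.zeros(2),
        }
        self.running_mean = np.zeros(f)
        self.running_var = np.ones(f)
        # per-bin input standardization, fitted on the training set; nWS
        # densities span several orders of magnitude across the frequency
        # axis, so the conv stack sees z-scored bins
        self.feature_mean = np.zeros(self.input_len)
        self.feature_std = np.ones(self.input_len)

    # -- architecture arithmetic -------------------------------------------------
    def conv_param_count(self) -> int:
        return self.cfg.n_filters * self.cfg.kernel + self.cfg.n_filters

    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward / backward ------------------------------------------------------
    def _conv_windows(self, x: np.ndarray) -> np.ndarray:
        xw = np.lib.stride_tricks.sliding_window_view(x, self.cfg.kernel, axis=1)
        return xw[:, :: self.cfg.stride, :]  # (B, conv_len, kernel)

    def _forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None = None):
        p = self.params
        x = (x - self.feature_mean) / self.feature_std
        xw = self._conv_windows(x)
        z = np.einsum("blk,fk->bfl", xw, p["W1"]) + p["b1"][None, :, None]
        if training:
            mu = z.mean(axis=(0, 2))
            var = z.var(axis=(0, 2))
            m = z.shape[0] * z.shape[2]
            mom = 0.1
            self.running_mean = (1 - mom) * self.running_mean + mom * mu
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - mom) * self.running_var + mom * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _EPS)
        xhat = (z - mu[None, :, None]) * inv_std[None, :, None]
        a = p["gamma"][None, :, None] * xhat + p["beta"][None, :, None]
        h = np.maximum(a, 0.0)
        if training and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            drop_mask = (rng.random(h.shape) < keep) / keep
            hd = h * drop_mask
        else:
            drop_mask = None
            hd = h
        flat = hd.reshape(hd.shape[0], -1)
        logits = flat @ p["W2"] + p["b2"]
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        cache = (xw, xhat, inv_std, a, drop_mask, flat, probs)
        return probs, cache

    def _backward(self, y: np.ndarray, sample_w: np.ndarray, cache) -> dict:
        p = self.params
        xw, xhat, inv_std, a, drop_mask, flat, probs = cache
        b = len(y)
        wsum = sample_w.sum()
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits *= (sample_w / wsum)[:, None]
        grads = {
            "W2": flat.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dflat = dlogits @ p["W2"].T
        dhd = dflat.reshape(b, self.cfg.n_filters, self.conv_len)
        dh = dhd if drop_mask is None else dhd * drop_mask
        da = dh * (a > 0)
        grads["gamma"] = np.einsum("bfl,bfl->f", da, xhat)
        grads["beta"] = da.sum(axis=(0, 2))
        # batch-norm backward over the (batch, position) axes
        m = b * self.conv_len
        dxhat = da * p["gamma"][None, :, None]
        s1 = dxhat.sum(axis=(0, 2))
        s2 = np.einsum("bfl,bfl->f", dxhat, xhat)
        dz = (inv_std[None, :, None] / m) * (
            m * dxhat - s1[None, :, None] - xhat * s2[None, :, None]
        )
        grads["W1"] = np.einsum("bfl,blk->fk", dz, xw)
        grads["b1"] = dz.sum(axis=(0, 2))
        return grads

    @staticmethod
    def loss(probs: np.ndarray, y: np.ndarray, sample_w: np.ndarray) -> float:
        ce = -np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))
        return float((sample_w * ce).sum() / sample_w.sum())

    # -- inference ---------------------------------------------------------------
    def check_axis(self, freqs_mm: np.ndarray) -> None:
        if self.freqs_mm is not None and not (
            len(freqs_mm) == len(self.freqs_mm) and np.allclose(freqs_mm, self.freqs_mm)
        ):
            raise ShapeError("spectrum frequency axis differs from the model's training axis")

    def predict_proba(self, spectra, chunk: int = 4096) -> np.ndarray:
        """Blur-class probability for each spectrum (dropout inactive,
        batch-normalization in inference mode; results independent of how
        the input is batched)."""
        x = as_matrix(spectra, self)
        out = np.empty(len(x))
        for s in range(0, len(x), chunk):
            probs, _ = self._forward(x[s : s + chunk], training=False)
            out[s : s + chunk] = probs[:, 1]
        return out

    # -- persistence -------------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arch = {
            "config": asdict(self.cfg),
            "input_len": self.input_len,
            "freqs_mm": None if self.freqs_mm is None else self.freqs_mm.tolist(),
            "metadata": self.metadata,
        }
        with open(directory / "architecture.json", "w") as fh:
            json.dump(arch, fh, indent=1)
        np.savez(
            directory / "weights.npz",
            running_mean=self.running_mean,
            running_var=self.running_var,
            feature_mean=self.feature_mean,
            feature_std=self.feature_std,
            **self.params,
        )
        pd.DataFrame(self.training_log).to_csv(directory / "training_log.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        with open(directory / "architecture.json") as fh:
            arch = json.load(fh)
        cfg = ClassifierConfig(**arch["config"])
        freqs = None if arch["freqs_mm"] is None else np.asarray(arch["freqs_mm"])
        model = cls(cfg, arch["input_len"], freqs)
        with np.load(directory / "weights.npz") as data:
            for key in model.params:
                model.params[key] = data[key]
            model.running_mean = data["running_mean"]
            model.running_var = data["running_var"]
            model.feature_mean = data["feature_mean"]
            model.feature_std = data["feature_std"]
        model.metadata = arch["metadata"]
        log_path = directory / "training_log.csv"
        if log_path.exists() and log_path.stat().st_size > 1:
            df = pd.read_csv(log_path)
            model.training_log = df.to_dict("records") if len(df) else []
        return model


def build_model(
    cfg: ClassifierConfig | None = None,
    input_len: int = 100,
    freqs_mm: np.ndarray | None = None,
) -> TrainedModel:
    """Seeded, untrained model; two builds from one seed are identical."""
    cfg = cfg or ClassifierConfig()
    if freqs_mm is not None:
        input_len = len(freqs_mm)
    return TrainedModel(cfg, input_len, freqs_mm)


def as_matrix(spectra, model: TrainedModel | None = None) -> np.ndarray:
    """Coerce records / spectra / arrays to a (n, input_len) float matrix,
    validating the frequency axis against the model when one is given."""
    if isinstance(spectra, np.ndarray):
        x = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    else:
        rows, axes = [], []
        for item in spectra:
            spec = item.spectrum if isinstance(item, WindowRecord) else item
            if not isinstance(spec, NwsSpectrum):
                raise ShapeError(f"cannot interpret {type(item)} as a spectrum")
            rows.append(spec.values)
            axes.append(spec.freqs_mm)
        if model is not None:
            for ax in axes:
                model.check_axis(ax)
        x = np.asarray(rows, dtype=np.float64)
    if model is not None and x.shape[1] != model.input_len:
        raise ShapeError(f"spectra length {x.shape[1]} != model input_len {model.input_len}")
    return x


def _labels_of(records) -> np.ndarray:
    y = []
    for rec in records:
        if rec.label not in _LABEL_TO_INT:
            raise ConfigurationError(f"record without a valid label: {rec.label!r}")
        y.append(_LABEL_TO_INT[rec.label])
    return np.asarray(y, dtype=np.int64)


def train(
    model: TrainedModel,
    train_records,
    val_records,
    weights: dict[str, float] | None = None,
    cfg: ClassifierConfig | None = None,
) -> TrainedModel:
    """Fit with Adam on class-weighted cross-entropy; early-stop on
    validation loss and return the best-validation parameters.

    ``train_records``/``val_records`` may be WindowRecord lists or
    ``(X, y)`` tuples.  Patient overlap between the two record lists raises
    :class:`IntegrityError`.
    """
    cfg = cfg or model.cfg
    if isinstance(train_records, tuple):
        x_tr, y_tr = train_records
        x_va, y_va = val_records
        x_tr, x_va = as_matrix(x_tr, model), as_matrix(x_va, model)
        y_tr, y_va = np.asarray(y_tr), np.asarray(y_va)
    else:
        tr_pat = {r.patient_id for r in train_records}
        va_pat = {r.patient_id for r in val_records}
        leaked = tr_pat & va_pat
        if leaked:
            raise IntegrityError(f"patients in both train and val: {sorted(leaked)[:5]}")
        x_tr, y_tr = as_matrix(train_records, model), _labels_of(train_records)
        x_va, y_va = as_matrix(val_records, model), _labels_of(val_records)
    if len(np.unique(y_tr)) < 2:
        raise ConfigurationError("training data contains a single class")
    model.feature_mean = x_tr.mean(axis=0)
    model.feature_std = np.maximum(x_tr.std(axis=0), 1e-12)
    if weights is None:
        weights = _class_weights({"sharp": int((y_tr == 0).sum()), "blurred": int((y_tr == 1).sum())})
    w_by_class = np.array([weights.get("sharp", 1.0), weights.get("blurred", 1.0)])

    rng = np.random.default_rng(cfg.seed)
    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_state = None
    bad_epochs = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        train_loss_acc = 0.0
        weight_acc = 0.0
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            wb = w_by_class[yb]
            probs, cache = model._forward(xb, training=True, rng=rng)
            grads = model._backward(yb, wb, cache)
            train_loss_acc += model.loss(probs, yb, wb) * wb.sum()
            weight_acc += wb.sum()
            step += 1
            for key, g in grads.items():
                adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * g
                adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * g * g
                m_hat = adam_m[key] / (1 - beta1**step)
                v_hat = adam_v[key] / (1 - beta2**step)
                model.params[key] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        val_probs = _eval_probs(model, x_va)
        val_loss = model.loss(val_probs, y_va, w_by_class[y_va])
        train_loss = train_loss_acc / max(weight_acc, 1e-12)
        model.training_log.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = (
                copy.deepcopy(model.params),
                model.running_mean.copy(),
                model.running_var.copy(),
            )
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    if best_state is not None:
        model.params, model.running_mean, model.running_var = best_state
    model.metadata["epochs_run"] = len(model.training_log)
    model.metadata["final_losses"] = {
        "best_val_loss": float(best_val),
        "last_train_loss": float(model.training_log[-1]["train_loss"]),
    }
    return model


def _eval_probs(model: TrainedModel, x: np.ndarray, chunk: int = 8192) -> np.ndarray:
    out = np.empty((len(x), 2))
    for s in range(0, len(x), chunk):
        probs, _ = model._forward(x[s : s + chunk], training=False)
        out[s : s + chunk] = probs
    return out


def grid_search(
    records,
    param_grid: dict[str, list],
    base_cfg: ClassifierConfig | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[ClassifierConfig, pd.DataFrame]:
    """Cross-validated hyperparameter selection.

    Every combination in ``param_grid`` (e.g. ``{"n_filters": [...],
    "dropout": [...], "learning_rate": [...]}``) is scored by the mean
    held-out-fold AUROC over a patient-stratified k-fold plan; the best
    combination wins.
    """
    from itertools import product

    from .evaluation import auroc

    base_cfg = base_cfg or ClassifierConfig()
    plan = make_splits(records, fractions=(1.0, 0.0), k_folds=k_folds, seed=seed)
    results = []
    keys = sorted(param_grid)
    for combo in product(*(param_grid[k] for k in keys)):
        cfg = ClassifierConfig(**{**asdict(base_cfg), **dict(zip(keys, combo))})
        fold_scores = []
        for fold in range(k_folds):
            va = [r for r in records if plan.folds.get(r.patient_id) == fold]
            tr = [r for r in records if plan.folds.get(r.patient_id, -1) not in (-1, fold)]
            if not va or len({r.label for r in tr}) < 2 or len({r.label for r in va}) < 2:
                continue
            model = build_model(cfg, freqs_mm=tr[0].spectrum.freqs_mm)
            train(model, tr, va, cfg=cfg)
            scores = model.predict_proba(va)
            fold_scores.append(auroc(scores, _labels_of(va)))
        row = dict(zip(keys, combo))
        row["mean_auroc"] = float(np.mean(fold_scores)) if fold_scores else np.nan
        results.append(row)
    table = pd.DataFrame(results)
    best_row = table.loc[table["mean_auroc"].idxmax()]
    best_cfg = ClassifierConfig(
        **{**asdict(base_cfg), **{k: _coerce(best_row[k], getattr(base_cfg, k)) for k in keys}}
    )
    return best_cfg, table


def _coerce(value, like):
    return type(like)(value)
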