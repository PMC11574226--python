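"""Statistical evaluation: bootstrap AUROC, agreement and association tests.

Covers the full evaluation protocol of the blur-detection study: AUROC by
the rank statistic with percentile bootstrap CIs and a one-sample t-test
against chance, threshold sweeps with per-cell bootstrap CIs, balanced
(inverse-frequency weighted) accuracy, Cohen's kappa for inter-rater and
model-vs-reader agreement, the chi-squared test of independence for
view/laterality contingency tables, Spearman rank correlation, and the
Shapiro-Wilk normality check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedMetricError


@dataclass
class ConfusionMatrix:
    """2x2 confusion counts with ``blurred`` as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive_class: str = "blurred"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise UndefinedMetricError("confusion counts must be non-negative")
        if self.total == 0:
            raise UndefinedMetricError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("no positive samples: sensitivity undefined")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise UndefinedMetricError("no negative samples: specificity undefined")
        return self.tn / (self.tn + self.fp)

    def as_table(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=np.int64)


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.min() < 0 or self.counts.sum() == 0:
            raise UndefinedMetricError("contingency table must be 2-D, non-negative, non-empty")


@dataclass
class EvalConfig:
    n_bootstrap: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    yates_correction_2x2: bool = True

    def __post_init__(self) -> None:
        if self.n_bootstrap < 100:
            raise ConfigurationError("n_bootstrap must be >= 100")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigurationError("ci_level must lie in (0, 1)")


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """AUROC by the Mann-Whitney rank statistic; ties get half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties -> 0.5 credit
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auroc_bootstrap(scores, labels, cfg: EvalConfig | None = None):
    """Point AUROC, percentile bootstrap CI and a one-sample t-test of the
    bootstrap distribution against 0.5 (one-sided, AUROC > 0.5).

    Returns ``(auroc, ci_low, ci_high, p_value)``.
    """
    cfg = cfg or EvalConfig()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = auroc(scores, labels)
    rng = np.random.default_rng(cfg.seed)
    n = len(scores)
    boot = np.empty(cfg.n_bootstrap)
    for b in range(cfg.n_bootstrap):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if 0 < lab.sum() < n:  # resample must contain both classes
                break
        boot[b] = auroc(scores[idx], lab)
    alpha = 1.0 - cfg.ci_level
    ci_low, ci_high = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    if np.ptp(boot) == 0:
        p_value = 0.0 if boot[0] > 0.5 else 1.0
    else:
        p_value = float(stats.ttest_1samp(boot, 0.5, alternative="greater").pvalue)
    return point, float(ci_low), float(ci_high), p_value


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between the two raters of a 2x2 table."""
    n = cm.total
    po = (cm.tp + cm.tn) / n
    p_row = ((cm.tp + cm.fn) / n, (cm.fp + cm.tn) / n)
    p_col = ((cm.tp + cm.fp) / n, (cm.fn + cm.tn) / n)
    pe = p_row[0] * p_col[0] + p_row[1] * p_col[1]
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def weighted_accuracy(cm: ConfusionMatrix) -> float:
    """Inverse-frequency weighted accuracy.

    With class weights inversely proportional to class frequency this
    reduces to balanced accuracy, (sensitivity + specificity) / 2.
    """
    return 0.5 * (cm.sensitivity + cm.specificity)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def chi2_independence(table: ContingencyTable, cfg: EvalConfig | None = None):
    """Pearson chi-squared test of independence.

    Yates continuity correction is applied on 2x2 tables when configured
    (the default).  Returns ``(statistic, dof, p)``.
    """
    cfg = cfg or EvalConfig()
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise UndefinedMetricError("zero marginal: degenerate contingency table")
    correction = cfg.yates_correction_2x2 and counts.shape == (2, 2)
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=correction)
    if (expected <= 0).any():
        raise UndefinedMetricError("expected counts must be positive")
    return float(chi2), int(dof), float(p)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties; two-sided p by the
    t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UndefinedMetricError("spearman_rho needs paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("constant vector: correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def normality_test(x) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ConfigurationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionMatrix:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (labels == 1))),
        fn=int(np.sum(~pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
    )


def threshold_sweep(
    scores, labels, thresholds, cfg: EvalConfig | None = None
) -> pd.DataFrame:
    """Confusion matrix and class-conditional rates per threshold, with
    percentile-bootstrap CIs on the rates.

    The row maximizing TPR + TNR (Youden's J) is flagged in the ``chosen``
    column — the operating point with the highest combined true-positive
    and true-negative percentage.
    """
    cfg = cfg or EvalConfig()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.sum() in (0, len(labels)):
        raise UndefinedMetricError("threshold sweep needs both classes present")
    rng = np.random.default_rng(cfg.seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    # stratified bootstrap keeps both rates defined in every resample
    boot_pos = rng.integers(0, len(pos_idx), size=(cfg.n_bootstrap, len(pos_idx)))
    boot_neg = rng.integers(0, len(neg_idx), size=(cfg.n_bootstrap, len(neg_idx)))
    alpha = 1.0 - cfg.ci_level

    rows = []
    for thr in thresholds:
        cm = confusion_at_threshold(scores, labels, thr)
        tpr_boot = (scores[pos_idx][boot_pos] >= thr).mean(axis=1)
        tnr_boot = (scores[neg_idx][boot_neg] < thr).mean(axis=1)
        tpr_ci = np.quantile(tpr_boot, [alpha / 2, 1 - alpha / 2])
        tnr_ci = np.quantile(tnr_boot, [alpha / 2, 1 - alpha / 2])
        tpr = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else np.nan
        tnr = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else np.nan
        rows.append(
            {
                "threshold": float(thr),
                "tp": cm.tp,
                "fn": cm.fn,
                "fp": cm.fp,
                "tn": cm.tn,
                "tpr": tpr,
                "tnr": tnr,
                "tpr_ci_low": float(tpr_ci[0]),
                "tpr_ci_high": float(tpr_ci[1]),
                "tnr_ci_low": float(tnr_ci[0]),
                "tnr_ci_high": float(tnr_ci[1]),
            }
        )
    df = pd.DataFrame(rows)
    youden = df["tpr"] + df["tnr"]
    df["chosen"] = youden == youden.max()
    return df


def image_level_confusion(verdict_labels, truth_labels) -> ConfusionMatrix:
    """Confusion counts from blurred/sharp label sequences."""
    v = np.asarray([lbl == "blurred" for lbl in verdict_labels])
    t = np.asarray([lbl == "blurred" for lbl in truth_labels])
    return ConfusionMatrix(
        tp=int(np.sum(v & t)),
        fn=int(np.sum(~v & t)),
        fp=int(np.sum(v & ~t)),
        tn=int(np.sum(~v & ~t)),
    )
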