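"""Bootstrap AUROC, agreement statistics and association tests."""

import numpy as np
import pytest
from scipy import stats

from mammoblur.errors import ConfigurationError, UndefinedMetricError
from mammoblur.evaluation import (
    ConfusionMatrix,
    ContingencyTable,
    EvalConfig,
    auroc,
    auroc_bootstrap,
    chi2_independence,
    cohens_kappa,
    confusion_at_threshold,
    normality_test,
    spearman_rho,
    threshold_sweep,
    weighted_accuracy,
)

FAST_BOOT = EvalConfig(n_bootstrap=500, seed=0)


class TestAuroc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        point, lo, hi, p = auroc_bootstrap(scores, labels, FAST_BOOT)
        assert point == 1.0 and lo == 1.0 and hi == 1.0
        assert p < 0.001

    def test_all_ties_give_half(self):
        scores = np.full(30, 0.4)
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        assert auroc(scores, labels) == 0.5

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert 0.45 <= auroc(scores, labels) <= 0.55

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(120), 2)  # many ties
        labels = rng.integers(0, 2, 120)
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auroc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            auroc(np.random.rand(5), np.ones(5, int))

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (200, 3200):  # 16x samples -> ~4x narrower CI
            scores = np.r_[rng.normal(0, 1, n // 2), rng.normal(1, 1, n // 2)]
            labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
            _, lo, hi, _ = auroc_bootstrap(scores, labels, FAST_BOOT)
            widths.append(hi - lo)
        assert widths[1] < widths[0] / 2.5


class TestAgreement:
    def test_model_vs_reader1_kappa(self):
        # 26/32 true positives and 97/127 true negatives
        assert round(cohens_kappa(ConfusionMatrix(26, 6, 30, 97)), 2) == 0.45

    def test_reader2_vs_reader1_kappa(self):
        # 17/32 and 121/127
        assert round(cohens_kappa(ConfusionMatrix(17, 15, 6, 121)), 2) == 0.54

    def test_perfect_diagonal(self):
        assert cohens_kappa(ConfusionMatrix(10, 0, 0, 20)) == 1.0

    def test_rater_swap_invariance(self):
        # transposing the table swaps fn <-> fp
        rng = np.random.default_rng(2)
        for _ in range(20):
            tp, fn, fp, tn = rng.integers(1, 50, 4)
            a = cohens_kappa(ConfusionMatrix(tp, fn, fp, tn))
            b = cohens_kappa(ConfusionMatrix(tp, fp, fn, tn))
            assert a == pytest.approx(b)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(3)
        kappas = []
        for _ in range(200):
            r1 = rng.integers(0, 2, 400).astype(bool)
            r2 = rng.integers(0, 2, 400).astype(bool)
            cm = ConfusionMatrix(
                tp=int(np.sum(r1 & r2)),
                fn=int(np.sum(r1 & ~r2)),
                fp=int(np.sum(~r1 & r2)),
                tn=int(np.sum(~r1 & ~r2)),
            )
            kappas.append(cohens_kappa(cm))
        assert abs(np.mean(kappas)) < 0.01

    def test_matches_sklearn_on_random_tables(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        for _ in range(10):
            r1 = rng.integers(0, 2, 100)
            r2 = rng.integers(0, 2, 100)
            cm = ConfusionMatrix(
                tp=int(np.sum((r1 == 1) & (r2 == 1))),
                fn=int(np.sum((r1 == 1) & (r2 == 0))),
                fp=int(np.sum((r1 == 0) & (r2 == 1))),
                tn=int(np.sum((r1 == 0) & (r2 == 0))),
            )
            assert cohens_kappa(cm) == pytest.approx(
                sklearn_metrics.cohen_kappa_score(r1, r2)
            )


class TestWeightedAccuracy:
    def test_perfect_classifier(self):
        assert weighted_accuracy(ConfusionMatrix(10, 0, 0, 30)) == 1.0

    def test_model_vs_reader1_counts(self):
        # balanced accuracy from the printed counts; the study's own
        # weighted-accuracy figure (0.840) uses an unpublished formula
        value = weighted_accuracy(ConfusionMatrix(26, 6, 30, 97))
        assert value == pytest.approx((26 / 32 + 97 / 127) / 2)
        assert value == pytest.approx(0.788, abs=5e-4)

    def test_equal_rates_fixed_point(self):
        cm = ConfusionMatrix(70, 30, 30, 70)
        assert weighted_accuracy(cm) == pytest.approx(0.7)


class TestChi2:
    def test_laterality_table_yates(self):
        table = ContingencyTable(np.array([[60, 98], [310, 296]]))
        _, dof, p = chi2_independence(table, EvalConfig())
        assert dof == 1
        assert round(p, 3) == 0.004

    def test_view_table_significant(self):
        table = ContingencyTable(np.array([[24, 134], [306, 300]]))
        _, _, p = chi2_independence(table, EvalConfig())
        assert p < 0.001

    def test_proportional_rows_null(self):
        table = ContingencyTable(np.array([[10, 20], [30, 60]]))
        cfg = EvalConfig(yates_correction_2x2=False)
        chi2, _, p = chi2_independence(table, cfg)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_uncorrected_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        cfg = EvalConfig(yates_correction_2x2=False)
        for _ in range(10):
            counts = rng.integers(20, 200, size=(3, 4))
            chi2, dof, _ = chi2_independence(ContingencyTable(counts), cfg)
            total = counts.sum()
            expected = np.outer(counts.sum(1), counts.sum(0)) / total
            oracle = ((counts - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(oracle)
            assert dof == 6

    def test_zero_marginal_raises(self):
        with pytest.raises(UndefinedMetricError):
            chi2_independence(ContingencyTable(np.array([[0, 0], [5, 5]])))


class TestCorrelationAndNormality:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        rho, _ = spearman_rho(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([10.0, 20.0, 20.0, 40.0])
        rho, _ = spearman_rho(x, y)
        rx = stats.rankdata(x)  # midranks
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle)

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedMetricError):
            spearman_rho(np.ones(5), np.arange(5.0))

    def test_normal_sample_calibration(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(500)
            _, p = normality_test(x)
            hits += p > 0.05
        assert hits >= 18  # >= 90% of seeds

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(0).exponential(size=500)
        W, p = normality_test(x)
        assert p < 0.001 and W < 0.95

    def test_sample_size_bounds(self):
        with pytest.raises(ConfigurationError):
            normality_test(np.array([1.0, 2.0]))
        with pytest.raises(ConfigurationError):
            normality_test(np.zeros(5001))


class TestThresholdSweep:
    def test_extreme_thresholds(self):
        rng = np.random.default_rng(6)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        df = threshold_sweep(scores, labels, [0.0, 1.0 + 1e-9], FAST_BOOT)
        assert df.iloc[0]["tnr"] == 0.0 and df.iloc[0]["tpr"] == 1.0
        assert df.iloc[1]["tpr"] == 0.0 and df.iloc[1]["tnr"] == 1.0

    def test_separable_scores_flag_perfect_threshold(self):
        scores = np.r_[np.random.default_rng(7).uniform(0, 0.3, 50),
                       np.random.default_rng(8).uniform(0.7, 1.0, 50)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        df = threshold_sweep(scores, labels, np.linspace(0.05, 0.95, 19), FAST_BOOT)
        chosen = df[df["chosen"]]
        assert ((chosen["tpr"] == 1.0) & (chosen["tnr"] == 1.0)).all()

    def test_ci_bounds_bracket_rates(self):
        rng = np.random.default_rng(9)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        df = threshold_sweep(scores, labels, [0.5], FAST_BOOT)
        row = df.iloc[0]
        assert row["tpr_ci_low"] <= row["tpr"] <= row["tpr_ci_high"]
        assert row["tnr_ci_low"] <= row["tnr"] <= row["tnr_ci_high"]


def test_confusion_at_threshold_counts():
    scores = np.array([0.2, 0.5, 0.8, 0.9])
    labels = np.array([0, 1, 0, 1])
    cm = confusion_at_threshold(scores, labels, 0.5)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 0, 1, 1)
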