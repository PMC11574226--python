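"""Window enumeration, labelling, patient-stratified splits, class weights."""

import numpy as np
import pytest

from mammoblur.dataset import (
    GridWindow,
    WindowGridConfig,
    WindowRecord,
    class_weights,
    enumerate_windows,
    frame_to_records,
    label_window,
    make_splits,
    records_to_frame,
    select_records,
)
from mammoblur.errors import ConfigurationError
from mammoblur.io import Mammogram
from mammoblur.nws import NwsSpectrum


def _mammo(shape):
    return Mammogram(np.zeros(shape), 0.05, "L", "CC")


def _record(pid, label=None, k=0):
    spec = NwsSpectrum(freqs_mm=np.arange(1, 4.0), values=np.ones(3))
    return WindowRecord(f"{pid}_img{k}", pid, (0, k), spec, label)


class TestEnumerateWindows:
    def test_full_mask_lattice(self):
        wins = enumerate_windows(_mammo((1000, 1000)), np.ones((1000, 1000), bool))
        assert len(wins) == 25  # 5 x 5 lattice of 200-px windows
        coords = {(w.i, w.j) for w in wins}
        assert coords == {(i, j) for i in range(5) for j in range(5)}

    def test_empty_mask(self):
        assert enumerate_windows(_mammo((1000, 1000)), np.zeros((1000, 1000), bool)) == []

    def test_half_masked_image(self):
        mask = np.zeros((1000, 1000), bool)
        mask[:, :500] = True
        wins = enumerate_windows(_mammo((1000, 1000)), mask)
        # columns 0-199 and 200-399 fully covered; 400-599 is half covered
        assert len(wins) == 10
        assert all(w.j in (0, 1) for w in wins)

    @pytest.mark.parametrize("seed", range(3))
    def test_coverage_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((600, 600)) > 0.3
        cfg = WindowGridConfig(window_px=150, stride_px=75, min_mask_fraction=0.6)
        wins = {(w.i, w.j) for w in enumerate_windows(_mammo((600, 600)), mask, cfg)}
        expected = set()
        for i, r0 in enumerate(range(0, 600 - 150 + 1, 75)):
            for j, c0 in enumerate(range(0, 600 - 150 + 1, 75)):
                if mask[r0 : r0 + 150, c0 : c0 + 150].mean() >= 0.6:
                    expected.add((i, j))
        assert wins == expected

    def test_lattice_to_pixel_bijection(self):
        cfg = WindowGridConfig(window_px=100, stride_px=50)
        wins = enumerate_windows(_mammo((400, 400)), np.ones((400, 400), bool), cfg)
        for w in wins:
            assert (w.r0, w.c0) == (w.i * 50, w.j * 50)


class TestLabelWindow:
    def test_threshold_rule(self):
        win = GridWindow(0, 0, 0, 0, 10)
        full = np.ones((20, 20), bool)
        assert label_window(win, full) == "blurred"
        partial = np.zeros((20, 20), bool)
        partial[:4, :10] = True  # 0.4 overlap < 0.5
        assert label_window(win, partial) == "sharp"

    def test_three_by_three_lattice_counts(self):
        """Polygon covering 4 windows fully and 2 at half: 6 blurred, 3 sharp."""
        blur = np.zeros((600, 600), bool)
        blur[:400, :500] = True
        cfg = WindowGridConfig(window_px=200)
        labels = []
        for i in range(3):
            for j in range(3):
                win = GridWindow(i, j, i * 200, j * 200, 200)
                labels.append(label_window(win, blur, cfg))
        assert labels.count("blurred") == 6
        assert labels.count("sharp") == 3

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pixel_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        blur = rng.random((300, 300)) > 0.5
        cfg = WindowGridConfig(window_px=100, blur_label_fraction=0.5)
        for i in range(3):
            for j in range(3):
                win = GridWindow(i, j, i * 100, j * 100, 100)
                frac = blur[i * 100 : (i + 1) * 100, j * 100 : (j + 1) * 100].mean()
                expected = "blurred" if frac >= 0.5 else "sharp"
                assert label_window(win, blur, cfg) == expected


class TestSplits:
    def _uniform_records(self, n_patients=10, per_patient=10):
        return [
            _record(f"P{p}", "sharp", k) for p in range(n_patients) for k in range(per_patient)
        ]

    def test_eighty_twenty_uniform(self):
        records = self._uniform_records()
        plan = make_splits(records, fractions=(0.8, 0.2), k_folds=0, seed=4)
        train = select_records(records, plan, "train")
        assert len(plan.patients("train")) == 8
        assert len(train) == 80

    def test_deterministic_given_seed(self):
        records = self._uniform_records()
        a = make_splits(records, seed=7)
        b = make_splits(records, seed=7)
        assert a == b
        c = make_splits(records, seed=8)
        assert a.assignment != c.assignment or a.folds != c.folds

    def test_folds_partition_patients(self):
        records = [_record(f"P{p}", "sharp", k) for p in range(25) for k in range(4)]
        plan = make_splits(records, fractions=(1.0, 0.0), k_folds=5, seed=1)
        assert set(plan.folds) == {f"P{p}" for p in range(25)}
        counts = np.bincount(list(plan.folds.values()), minlength=5)
        assert counts.sum() == 25 and counts.min() >= 1

    def test_no_patient_straddles_the_split(self):
        rng = np.random.default_rng(0)
        records = []
        for p in range(30):
            for k in range(int(rng.integers(1, 12))):
                records.append(_record(f"P{p}", "sharp", k))
        plan = make_splits(records, seed=3)
        for part in ("train", "test"):
            pats = {r.patient_id for r in select_records(records, plan, part)}
            assert pats == set(plan.patients(part))
        assert not set(plan.patients("train")) & set(plan.patients("test"))

    def test_realized_fraction_near_target(self):
        rng = np.random.default_rng(2)
        records = []
        for p in range(40):
            for k in range(int(rng.integers(2, 8))):
                records.append(_record(f"P{p}", "sharp", k))
        plan = make_splits(records, fractions=(0.8, 0.2), seed=5)
        frac = len(select_records(records, plan, "train")) / len(records)
        assert abs(frac - 0.8) <= 0.05

    def test_too_few_patients_raises(self):
        records = [_record(f"P{p}", "sharp") for p in range(3)]
        with pytest.raises(ConfigurationError):
            make_splits(records, k_folds=5, seed=0)

    def test_roundtrip_json(self, tmp_path):
        plan = make_splits(self._uniform_records(), seed=9)
        path = plan.to_json(tmp_path / "plan.json")
        from mammoblur.dataset import SplitPlan

        assert SplitPlan.from_json(path) == plan


class TestClassWeights:
    def test_clinical_scale_imbalance_ratio(self):
        w = class_weights({"blurred": 4379, "sharp": 125799})
        assert w["blurred"] / w["sharp"] == pytest.approx(125799 / 4379)
        assert (w["blurred"] + w["sharp"]) / 2 == pytest.approx(1.0)

    def test_balanced_counts_unit_weights(self):
        w = class_weights({"blurred": 50, "sharp": 50})
        assert w == {"blurred": 1.0, "sharp": 1.0}

    def test_one_three_normalization(self):
        w = class_weights({"blurred": 1, "sharp": 3})
        assert w["blurred"] == pytest.approx(1.5)
        assert w["sharp"] == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(ConfigurationError):
            class_weights({"sharp": 10})


def test_spectra_frame_roundtrip(tmp_path):
    records = [_record("P1", "blurred", 0), _record("P2", "sharp", 1)]
    df = records_to_frame(records)
    back = frame_to_records(df)
    assert [r.patient_id for r in back] == ["P1", "P2"]
    assert [r.label for r in back] == ["blurred", "sharp"]
    assert np.allclose(back[0].spectrum.values, records[0].spectrum.values)
    assert np.allclose(back[0].spectrum.freqs_mm, records[0].spectrum.freqs_mm)
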