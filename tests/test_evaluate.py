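"""Evaluation: stratified split, confusion tallies, SNR anchors,
sensitivity regression."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import eogkit as ek
from eogkit.types import CLASS_ORDER, ValidationError


class TestSplit:
    def test_1200_balanced_epochs_split_900_300(self, default_config):
        bench = ek.make_benchmark_dataset(200, default_config)
        train, test = ek.split_train_test(bench, 0.75, seed=0)
        assert len(train) == 900 and len(test) == 300
        assert set(train.class_counts().values()) == {150}
        assert set(test.class_counts().values()) == {50}

    def test_two_per_class_fraction_half(self):
        X = np.zeros((12, 2, 10))
        y = np.array(sorted(CLASS_ORDER * 2), dtype=object)
        train, test = ek.split_train_test(ek.EpochSet(X, y, 250.0), 0.5, seed=1)
        assert set(train.class_counts().values()) == {1}
        assert set(test.class_counts().values()) == {1}

    def test_same_seed_identical_partition(self, small_bench):
        t1, s1 = ek.split_train_test(small_bench, 0.75, seed=9)
        t2, s2 = ek.split_train_test(small_bench, 0.75, seed=9)
        np.testing.assert_array_equal(t1.X, t2.X)
        np.testing.assert_array_equal(s1.X, s2.X)

    def test_disjoint_and_exhaustive(self, small_bench):
        train, test = ek.split_train_test(small_bench, 0.6, seed=2)
        assert len(train) + len(test) == len(small_bench)
        # reconstruct: every original epoch appears exactly once
        allX = np.concatenate([train.X, test.X])
        assert allX.shape[0] == small_bench.X.shape[0]

    @pytest.mark.parametrize("fraction", [0.25, 0.5, 0.75, 0.9])
    def test_total_train_count_is_rounded_fraction(self, small_bench, fraction):
        train, _ = ek.split_train_test(small_bench, fraction, seed=3)
        assert len(train) == round(fraction * len(small_bench))

    def test_class_below_two_members_errors(self):
        X = np.zeros((7, 2, 10))
        y = np.array(["D", "L", "N", "R", "U", "B", "D"], dtype=object)
        with pytest.raises(ValidationError, match="fewer than 2"):
            ek.split_train_test(ek.EpochSet(X, y, 250.0), 0.75, seed=0)


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = np.array(list(CLASS_ORDER) * 50, dtype=object)
        cm = ek.confusion_and_accuracy(y, y)
        assert cm.accuracy == 1.0
        assert np.trace(cm.counts) == 300
        assert cm.counts.sum() == 300

    def test_all_null_predictions_on_balanced_truth(self):
        y = np.array(list(CLASS_ORDER) * 10, dtype=object)
        preds = np.array(["N"] * 60, dtype=object)
        cm = ek.confusion_and_accuracy(y, preds)
        assert cm.accuracy == pytest.approx(1 / 6)

    def test_hand_tallied_example(self):
        truth = ["U", "U", "D", "L", "R", "B", "N", "N", "U", "L", "B", "R"]
        preds = ["U", "D", "D", "L", "R", "B", "N", "U", "U", "L", "B", "L"]
        cm = ek.confusion_and_accuracy(truth, preds)
        idx = {c: i for i, c in enumerate(CLASS_ORDER)}
        expected = np.zeros((6, 6), dtype=int)
        for t, p in zip(truth, preds):
            expected[idx[t], idx[p]] += 1
        np.testing.assert_array_equal(cm.counts, expected)
        assert cm.accuracy == pytest.approx(9 / 12)
        assert cm.per_class_accuracy["U"] == pytest.approx(2 / 3)

    def test_row_and_column_sums_conserved(self, rng):
        truth = rng.choice(CLASS_ORDER, size=200)
        preds = rng.choice(CLASS_ORDER, size=200)
        cm = ek.confusion_and_accuracy(truth, preds)
        for i, c in enumerate(CLASS_ORDER):
            assert cm.counts[i].sum() == np.sum(truth == c)
            assert cm.counts[:, i].sum() == np.sum(preds == c)

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValidationError, match="'X'"):
            ek.confusion_and_accuracy(["U"], ["X"])
        with pytest.raises(ValidationError, match="length"):
            ek.confusion_and_accuracy(["U", "D"], ["U"])


def _synthetic_snr_recording(ratio, fs=250.0):
    """One 5-s segment whose event rms is exactly `ratio` x null rms."""
    n = int(5 * fs)
    x = np.zeros(n)
    t = np.arange(n) / fs
    # null span: unit-rms square wave +-1 alternating each sample
    noise = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    x[:] = noise
    # event span 1..2 s: square wave of amplitude `ratio`
    ev = slice(int(1 * fs), int(2 * fs))
    x[ev] = ratio * noise[ev]
    rec = ek.EOGRecording(np.vstack([x, np.zeros(n)]), fs)
    track = ek.LabelTrack([ek.GazeEvent("R", 1.0, 1.0, 10.0)], rec.duration)
    return rec, track


class TestSNR:
    def test_ratio_ten_gives_10_db_under_rms_formula(self):
        # SNR(dB) = 10*log10(rms ratio): ratio 10 -> 10 dB, ratio 100 -> 20 dB
        rec, track = _synthetic_snr_recording(10.0)
        rep = ek.snr_analysis(rec, track, segment_s=5.0, n_segments=1, stage="raw")
        assert rep.snr_db == pytest.approx(10.0, abs=1e-9)
        rec2, track2 = _synthetic_snr_recording(100.0)
        rep2 = ek.snr_analysis(rec2, track2, segment_s=5.0, n_segments=1, stage="raw")
        assert rep2.snr_db == pytest.approx(20.0, abs=1e-9)

    def test_equal_rms_gives_0_db(self):
        rec, track = _synthetic_snr_recording(1.0)
        rep = ek.snr_analysis(rec, track, segment_s=5.0, n_segments=1, stage="raw")
        assert rep.snr_db == pytest.approx(0.0, abs=1e-9)

    def test_default_protocol_matches_gold_electrode_value(self, default_config):
        rec, labels = ek.make_snr_recording(default_config)
        rep = ek.snr_analysis(rec, labels)
        assert rep.snr_db == pytest.approx(22.1, abs=1.7)
        assert len(rep.per_segment_db) == 5
        for rs_db in rep.per_segment_db:
            assert math.isfinite(rs_db)

    def test_scale_invariance(self, default_config):
        rec, labels = ek.make_snr_recording(default_config)
        rep1 = ek.snr_analysis(rec, labels)
        rep2 = ek.snr_analysis(rec.with_samples(rec.samples * 7.3), labels)
        assert rep2.snr_db == pytest.approx(rep1.snr_db, abs=1e-9)

    def test_segment_without_events_errors(self, default_config):
        rec, _ = ek.make_snr_recording(default_config, n_segments=2)
        empty = ek.LabelTrack([], rec.duration)
        with pytest.raises(ValidationError, match="lacks"):
            ek.snr_analysis(rec, empty, n_segments=2)

    def test_recording_shorter_than_segments_errors(self, default_config):
        rec, labels = ek.make_snr_recording(default_config, n_segments=2)
        with pytest.raises(ValidationError, match="required"):
            ek.snr_analysis(rec, labels, n_segments=10)


class TestSensitivity:
    ANGLES = [-30, -20, -10, 10, 20, 30]

    def test_noise_free_slope_exact(self, clean_config):
        rec, labels = ek.make_tracking_recording(self.ANGLES, clean_config)
        fit = ek.sensitivity_fit(rec, labels)
        assert fit.slope == pytest.approx(12.3, abs=1e-6)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)

    def test_zero_amplitude_gives_zero_slope(self, clean_config):
        flat = dataclasses.replace(clean_config, sensitivity=1e-12)
        rec, labels = ek.make_tracking_recording(self.ANGLES, flat)
        fit = ek.sensitivity_fit(rec, labels)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovered_within_5_percent_over_seeds(self, default_config):
        slopes = []
        for s in range(20):
            cfg = dataclasses.replace(default_config, seed=500 + s)
            rec, labels = ek.make_tracking_recording(self.ANGLES, cfg)
            slopes.append(ek.sensitivity_fit(rec, labels).slope)
        mean = float(np.mean(slopes))
        assert abs(mean - 12.3) / 12.3 < 0.05

    def test_fewer_than_three_angles_errors(self, clean_config):
        rec, labels = ek.make_tracking_recording([10, 20], clean_config)
        with pytest.raises(ValidationError, match="3 distinct"):
            ek.sensitivity_fit(rec, labels)


@given(st.floats(min_value=0.1, max_value=50.0))
def test_snr_db_formula_anchor(ratio):
    rec, track = _synthetic_snr_recording(ratio)
    rep = ek.snr_analysis(rec, track, segment_s=5.0, n_segments=1, stage="raw")
    assert rep.snr_db == pytest.approx(10 * math.log10(ratio), abs=1e-9)
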