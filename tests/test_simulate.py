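"""Simulator: waveform geometry, polarity, amplitude bounds, determinism."""

import dataclasses

import numpy as np
import pytest

import eogkit as ek
from eogkit.simulate import MAX_AMPLITUDE_UV
from eogkit.types import ValidationError


def _rec(script, config, **kw):
    rec, track = ek.synthesize_recording(script, config, **kw)
    return rec, track


class TestSaccadeWaveform:
    def test_rightward_saccade_plateau_matches_sensitivity_times_angle(self, clean_config):
        script = ek.GazeScript([ek.GazeEvent("R", 0.5, 0.4, 30.0)])
        rec, _ = _rec(script, clean_config, duration=1.5)
        mid = int(0.7 * clean_config.sample_rate)
        assert rec.horizontal[mid] == pytest.approx(12.3 * 30.0, abs=1e-6)
        assert np.abs(rec.vertical).max() == 0.0

    @pytest.mark.parametrize(
        "label,channel,sign",
        [("R", 0, 1), ("L", 0, -1), ("U", 1, 1), ("D", 1, -1)],
    )
    def test_polarity_convention(self, clean_config, label, channel, sign):
        script = ek.GazeScript([ek.GazeEvent(label, 0.5, 0.4, 20.0)])
        rec, _ = _rec(script, clean_config, duration=1.5)
        extremum = rec.samples[channel][np.argmax(np.abs(rec.samples[channel]))]
        assert np.sign(extremum) == sign
        # the other channel stays exactly flat without noise
        assert np.abs(rec.samples[1 - channel]).max() == 0.0

    def test_blink_is_positive_biphasic_vertical_spike(self, clean_config):
        script = ek.GazeScript([ek.GazeEvent("B", 0.5, 0.25)])
        rec, _ = _rec(script, clean_config, duration=1.5)
        v = rec.vertical
        # peak is nominal amplitude minus a small undershoot-overlap term
        assert v.max() == pytest.approx(clean_config.blink_amplitude, rel=0.05)
        assert v.min() < -0.1 * clean_config.blink_amplitude  # undershoot lobe
        assert np.abs(rec.horizontal).max() == 0.0

    def test_empty_script_zero_noise_gives_all_zero_recording(self, clean_config):
        rec, track = _rec(ek.GazeScript([]), clean_config, duration=2.0)
        assert rec.n_samples == 500
        assert np.abs(rec.samples).max() == 0.0
        assert len(track) == 0


class TestValidationAndDeterminism:
    def test_same_seed_same_recording(self, default_config):
        script = ek.GazeScript([ek.GazeEvent("L", 0.5, 0.4, 15.0)])
        rec1, _ = _rec(script, default_config, duration=2.0)
        rec2, _ = _rec(script, default_config, duration=2.0)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            ek.GazeScript(
                [ek.GazeEvent("R", 0.5, 1.0, 10.0), ek.GazeEvent("L", 1.0, 1.0, 10.0)]
            )

    def test_angle_beyond_amplitude_ceiling_rejected(self, default_config):
        big = dataclasses.replace(default_config, sensitivity=60.0)
        script = ek.GazeScript([ek.GazeEvent("R", 0.5, 0.4, 55.0)])
        with pytest.raises(ValidationError, match="ceiling"):
            ek.synthesize_recording(script, big)

    def test_blink_must_dominate_vertical_saccades(self, default_config):
        weak = dataclasses.replace(default_config, blink_amplitude=100.0)
        script = ek.GazeScript(
            [ek.GazeEvent("U", 0.5, 0.4, 30.0), ek.GazeEvent("B", 2.0, 0.25)]
        )
        with pytest.raises(ValidationError, match="blink_amplitude"):
            ek.synthesize_recording(script, weak)

    def test_amplitude_bound_default_config(self, default_config):
        bench = ek.make_benchmark_dataset(20, default_config)
        assert np.abs(bench.X).max() <= MAX_AMPLITUDE_UV

    def test_invalid_config_values_rejected(self):
        with pytest.raises(ValidationError):
            ek.SimulatorConfig(sample_rate=0)
        with pytest.raises(ValidationError):
            ek.SimulatorConfig(noise_sigma=-1)
        with pytest.raises(ValidationError):
            ek.SimulatorConfig(sensitivity=0)


class TestBenchmarkDataset:
    def test_counts_and_balance(self, default_config):
        bench = ek.make_benchmark_dataset(4, default_config)
        assert len(bench) == 24
        assert set(bench.class_counts().values()) == {4}
        assert bench.window_samples == 250

    def test_u_epoch_vertical_dominates_horizontal(self, clean_config):
        bench = ek.make_benchmark_dataset(1, clean_config)
        u = bench.X[bench.y == "U"][0]
        assert np.abs(u[1]).max() > np.abs(u[0]).max()

    def test_same_seed_identical_tensors(self, default_config):
        b1 = ek.make_benchmark_dataset(3, default_config)
        b2 = ek.make_benchmark_dataset(3, default_config)
        np.testing.assert_array_equal(b1.X, b2.X)
        assert list(b1.y) == list(b2.y)

    def test_angles_within_requested_range(self, default_config):
        bench = ek.make_benchmark_dataset(10, default_config, angle_range=(10, 30))
        a = bench.angles[~np.isnan(bench.angles)]
        assert a.min() >= 10 and a.max() <= 30

    def test_label_conservation(self, default_config):
        script = ek.GazeScript(
            [
                ek.GazeEvent("R", 0.5, 0.4, 10.0),
                ek.GazeEvent("N", 1.5, 0.4),
                ek.GazeEvent("B", 3.0, 0.25),
            ]
        )
        _, track = ek.synthesize_recording(script, default_config)
        assert len(track.non_null()) == 2
        assert len(track) == 3


class TestTrackingRecording:
    def test_zero_angle_gives_flat_horizontal(self, clean_config):
        rec, _ = ek.make_tracking_recording([0.0], clean_config)
        assert np.abs(rec.horizontal).max() == 0.0

    def test_plateau_means_equal_sensitivity_times_angle(self, clean_config):
        angles = [-30, -20, -10, 10, 20, 30]
        rec, track = ek.make_tracking_recording(angles, clean_config)
        for e, a in zip(track, angles):
            i0 = int((e.onset + 0.25) * clean_config.sample_rate)
            i1 = int((e.end - 0.25) * clean_config.sample_rate)
            assert np.mean(rec.horizontal[i0:i1]) == pytest.approx(12.3 * a, abs=1e-6)

    def test_out_of_range_angle_rejected(self, default_config):
        with pytest.raises(ValidationError, match="60"):
            ek.make_tracking_recording([75.0], default_config)

    def test_plateau_duration_matches_fixation(self, clean_config):
        rec, track = ek.make_tracking_recording([15.0], clean_config, fixation_s=1.0)
        level = 12.3 * 15.0
        above = np.sum(rec.horizontal > level / 2)
        assert above == pytest.approx(250, abs=2)
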