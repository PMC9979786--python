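"""Preprocessing chain: filter response, DC rule, detrend, epoching."""

import numpy as np
import pytest
from scipy import signal as sps

import eogkit as ek
from eogkit.types import ValidationError


def _recording(arr, fs=250.0):
    arr = np.atleast_2d(arr)
    if arr.shape[0] == 1:
        arr = np.vstack([arr, np.zeros_like(arr)])
    return ek.EOGRecording(arr, fs)


class TestBandpass:
    def test_dc_attenuated_at_least_40_db(self):
        spec = ek.FilterSpec()
        w, h = sps.sosfreqz(spec.sos(250.0), worN=[1e-6, 0.01], fs=250.0)
        assert 20 * np.log10(np.abs(h[0]) + 1e-300) < -40

    def test_constant_input_driven_to_zero(self):
        rec = _recording(np.full(2500, 500.0))
        out = ek.bandpass_filter(rec)
        steady = out.samples[0, 500:-500]
        assert np.abs(steady).max() < 1.0

    def test_band_center_sinusoid_within_1_db(self):
        # geometric band center of 0.1-15 Hz
        f0 = np.sqrt(0.1 * 15.0)
        t = np.arange(0, 60, 1 / 250)
        rec = _recording(100 * np.sin(2 * np.pi * f0 * t))
        out = ek.bandpass_filter(rec)
        amp = np.abs(out.samples[0][5000:-5000]).max()
        gain_db = 20 * np.log10(amp / 100.0)
        assert abs(gain_db) < 1.0

    def test_zero_in_zero_out_and_linearity(self):
        rec = _recording(np.zeros(1000))
        assert np.abs(ek.bandpass_filter(rec).samples).max() == 0.0
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        a = ek.bandpass_filter(_recording(x)).samples
        b = ek.bandpass_filter(_recording(3.5 * x)).samples
        np.testing.assert_allclose(b, 3.5 * a, rtol=1e-9, atol=1e-9)

    def test_too_short_recording_errors_with_minimum_length(self):
        rec = _recording(np.zeros(10))
        with pytest.raises(ValidationError, match="minimum"):
            ek.bandpass_filter(rec)

    def test_fir_mode_preserves_band_center(self):
        spec = ek.FilterSpec(design="fir")
        f0 = np.sqrt(0.1 * 15.0)
        t = np.arange(0, 60, 1 / 250)
        rec = _recording(100 * np.sin(2 * np.pi * f0 * t))
        out = ek.bandpass_filter(rec, spec)
        amp = np.abs(out.samples[0][5000:-5000]).max()
        assert abs(20 * np.log10(amp / 100.0)) < 1.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            ek.FilterSpec(low_cutoff=15, high_cutoff=0.1)
        with pytest.raises(ValidationError):
            ek.FilterSpec(order=0)
        with pytest.raises(ValidationError):
            ek.FilterSpec(high_cutoff=200).validate_rate(250.0)


class TestRemoveDcOffset:
    def test_first_value_subtracted(self):
        rec = _recording(np.array([100.0, 120.0, 90.0]))
        out = ek.remove_dc_offset(rec)
        np.testing.assert_array_equal(out.samples[0], [0.0, 20.0, -10.0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        rec = _recording(rng.normal(50, 10, size=100))
        once = ek.remove_dc_offset(rec)
        twice = ek.remove_dc_offset(once)
        np.testing.assert_array_equal(once.samples, twice.samples)
        assert once.samples[0, 0] == 0.0

    def test_empty_recording_errors(self):
        with pytest.raises(ValidationError):
            ek.remove_dc_offset(ek.EOGRecording(np.empty((2, 0)), 250.0))


class TestDetrend:
    def test_exact_ramp_removed(self):
        t = np.arange(500, dtype=float)
        rec = _recording(3.0 + 0.25 * t)
        out = ek.detrend(rec)
        assert np.abs(out.samples[0]).max() < 1e-9

    def test_ramp_plus_sinusoid_matches_least_squares_oracle(self):
        n = 1000
        t = np.arange(n, dtype=float)
        sine = 10 * np.sin(2 * np.pi * t / 50.0)
        x = 5.0 + 0.1 * t + sine
        rec = _recording(x)
        out = ek.detrend(rec)
        # closed-form least-squares oracle for the removed line
        expected = x - np.polyval(np.polyfit(t, x, 1), t)
        assert np.abs(out.samples[0] - expected).max() < 1e-6
        # the oscillation itself survives detrending nearly intact
        corr = np.corrcoef(out.samples[0], sine)[0, 1]
        assert corr > 0.999

    def test_residual_slope_below_tolerance(self):
        rng = np.random.default_rng(2)
        rec = _recording(rng.normal(size=2000) + np.linspace(0, 50, 2000))
        out = ek.detrend(rec)
        x = out.samples[0]
        slope = np.polyfit(np.arange(len(x)), x, 1)[0]
        assert abs(slope) < 1e-9
        assert abs(x.mean()) < 1e-9

    def test_too_short_errors(self):
        with pytest.raises(ValidationError):
            ek.detrend(ek.EOGRecording(np.zeros((2, 1)), 250.0))


class TestEpochWindows:
    def _make(self, clean_config):
        events = [ek.GazeEvent("R", 1.0 + i, 0.4, 15.0) for i in range(6)]
        script = ek.GazeScript(events)
        return ek.synthesize_recording(script, clean_config, duration=10.0)

    def test_interior_events_all_kept(self, clean_config):
        rec, track = self._make(clean_config)
        epochs, excluded = ek.epoch_windows(rec, track, window_s=1.0)
        assert excluded == 0
        assert epochs.X.shape == (6, 2, 250)
        assert set(epochs.y) == {"R"}

    def test_edge_event_excluded_and_counted(self, clean_config):
        script = ek.GazeScript([ek.GazeEvent("R", 0.0, 0.4, 15.0)])
        rec, track = ek.synthesize_recording(script, clean_config, duration=5.0)
        epochs, excluded = ek.epoch_windows(rec, track, window_s=1.0)
        assert excluded == 1
        assert len(epochs) == 0

    def test_epochs_identical_when_label_file_order_permuted(self, clean_config, tmp_path):
        import pandas as pd

        from eogkit import io

        rec, track = self._make(clean_config)
        path = tmp_path / "labels.csv"
        io.write_labels(track, path)
        df = pd.read_csv(path).sample(frac=1.0, random_state=3)
        df.to_csv(path, index=False)
        permuted = io.read_labels(path, duration=rec.duration)
        epochs1, _ = ek.epoch_windows(rec, track)
        epochs2, _ = ek.epoch_windows(rec, permuted)
        np.testing.assert_array_equal(epochs1.X, epochs2.X)
        assert list(epochs1.y) == list(epochs2.y)

    def test_chain_preserves_length_and_channels(self, default_config):
        script = ek.GazeScript([ek.GazeEvent("U", 2.0, 0.4, 20.0)])
        rec, _ = ek.synthesize_recording(script, default_config, duration=6.0)
        out = ek.PreprocessPipeline().process_recording(rec)
        assert out.samples.shape == rec.samples.shape
        assert out.sample_rate == rec.sample_rate
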