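# eogkit

Simulation, preprocessing, classification and streaming control for
two-channel **electrooculography (EOG)** — the potential generated by the
corneo-retinal dipole that deflects with gaze direction. `eogkit` is aimed
at people building gaze-driven human–machine interfaces (wheelchairs,
robots, RC vehicles) and at anyone who needs a controlled, fully labeled
EOG test bed: it reproduces, end to end and headlessly, the signal chain
of a wearable dry-electrode EOG headband sampling at 250 Hz.

The package covers:

* **`eogkit.simulate`** — a calibrated synthetic EOG generator. Saccades
  are sigmoidal step deflections with plateau amplitude
  `s · θ` (sensitivity `s = 12.3 µV/°`, gaze angle `θ`), horizontal
  saccades on channel 1 (R positive, L negative), vertical on channel 2
  (U positive, D negative); blinks are brief biphasic vertical spikes;
  nuisance terms are sinusoidal drift, powerline interference and white
  noise, all seeded. Physiological amplitudes are kept inside
  0.05–3 mV.
* **`eogkit.preprocess`** — the fixed chain *bandpass (0.1–15 Hz,
  third-order Butterworth magnitude, zero phase) → DC-offset removal
  (subtract the first sample) → linear detrend → 1-s epoching*.
* **`eogkit.rule` / `eogkit.knn` / `eogkit.cnn`** — three six-class
  classifiers over `{U, D, L, R, B, N}` (up, down, left, right, blink,
  null) with a common fit/predict contract: calibrated magnitude
  thresholds, k-nearest neighbours (k = 5, Euclidean, deterministic
  tie-breaks), and a small 1D CNN (two convolutional modules with
  filters of decreasing size → flatten → dense-softmax) implemented
  directly on numpy and trained with Adam.
* **`eogkit.evaluate`** — stratified 75/25 splitting, 6×6 confusion
  matrices, segmented SNR `10·log10(rms_signal / rms_noise)` in dB, and
  the gaze-sensitivity regression (µV per degree).
* **`eogkit.stream`** — sliding-window real-time classification with
  vote/refractory debouncing, the gaze→command map
  U→FORWARD, D→REVERSE, L→CCW, R→CW, B→STOP (emergency stop, fast
  path), and a headless replay of a seven-maneuver driving track.

## Worked example

```python
import numpy as np
import eogkit as ek

config = ek.SimulatorConfig(seed=42)                 # 250 Hz, 12.3 µV/°
bench = ek.make_benchmark_dataset(200, config)       # 1200 labeled 1-s epochs
processed = ek.PreprocessPipeline().process_epochs(bench)
train, test = ek.split_train_test(processed, 0.75, seed=42)

for name, model in [
    ("rule", ek.RuleClassifier()),
    ("knn",  ek.KNNClassifier()),
    ("cnn",  ek.CNNClassifier(ek.CNNConfig(seed=42))),
]:
    acc = np.mean(model.fit(train).predict(test) == test.y)
    print(f"{name}: {100 * acc:.1f}%")

rec, labels = ek.make_snr_recording(config)
print(f"SNR: {ek.snr_analysis(rec, labels).snr_db:.1f} dB")

rec, labels = ek.make_tracking_recording([-30, -20, -10, 10, 20, 30], config)
print(f"sensitivity: {ek.sensitivity_fit(rec, labels).slope:.2f} uV/deg")
```

prints

```
rule: 100.0%
knn: 100.0%
cnn: 100.0%
SNR: 22.2 dB
sensitivity: 12.32 uV/deg
```

All three classifiers separate the calibrated synthetic benchmark
essentially perfectly — at the device-realistic noise floor the 123–369 µV
saccade deflections are far above the ~1.9 µV residual noise — while the
SNR and sensitivity numbers recover the values the generator was
calibrated to (22.1 dB, 12.3 µV/°). The streaming demo replays the
seven-maneuver track:

```python
result = ek.run_track_demo()
print(result.groups)   # (('FORWARD',), ('CCW', 'FORWARD'), ('CW',), ...)
print(result.passed)   # True
```

A `eogkit` console script exposes the same pipeline as subcommands
(`simulate`, `preprocess`, `train`, `predict`, `evaluate`, `snr`,
`sensitivity`, `stream`, `demo`); see `eogkit --help`.

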