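"""Synthetic two-channel EOG generation with ground-truth labels.

The waveform model reproduces the statistical structure of saccadic EOG
as recorded by a dry-electrode wearable at 250 Hz:

* a saccade toward a target at gaze angle ``a`` degrees is a step
  deflection of ``sensitivity * a`` microvolts (default sensitivity
  12.3 uV/deg) with a sigmoidal rise, held for the gaze duration and
  mirrored back to baseline;
* horizontal saccades (L/R) deflect channel 1 only (R positive, L
  negative); vertical saccades (U/D) deflect channel 2 only (U positive,
  D negative);
* a blink is a brief biphasic spike on the vertical channel, much larger
  than any scripted saccade so it stays separable from U;
* additive nuisance terms: slow sinusoidal baseline drift, powerline
  interference, and white Gaussian noise, all seeded from a single
  generator.

Physiological EOG amplitudes live between roughly 0.05 and 3 mV; the
simulator rejects any scripted saccade whose plateau would exceed 3 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .types import (
    EOGRecording,
    EpochSet,
    GazeEvent,
    GazeScript,
    LabelTrack,
    ValidationError,
)

#: Physiological EOG amplitude ceiling, microvolts.
MAX_AMPLITUDE_UV = 3000.0


@dataclass(frozen=True)
class SimulatorConfig:
    """All tunable parameters of the synthetic EOG generator.

    Amplitudes are microvolts, times seconds, rates Hz. The defaults are
    calibrated to the dry gold-electrode device being emulated: 12.3
    uV/deg gaze sensitivity, and a noise floor (white noise + powerline
    + drift) sized so the rms-ratio SNR of the left/right gaze protocol
    comes out near 22 dB.
    """

    sample_rate: float = 250.0
    sensitivity: float = 12.3
    saccade_rise_time: float = 0.04
    blink_amplitude: float = 800.0
    blink_duration: float = 0.25
    drift_amplitude: float = 15.0
    drift_period: float = 30.0
    powerline_freq: float = 60.0
    powerline_amplitude: float = 0.8
    noise_sigma: float = 1.65
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if not self.sensitivity > 0:
            raise ValidationError(f"sensitivity must be > 0, got {self.sensitivity}")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        for name in ("saccade_rise_time", "blink_duration", "drift_period"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("blink_amplitude", "drift_amplitude", "powerline_amplitude"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def noiseless(self) -> "SimulatorConfig":
        """A copy with every nuisance term switched off (pure waveforms)."""
        return replace(
            self, drift_amplitude=0.0, powerline_amplitude=0.0, noise_sigma=0.0
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _saccade_pulse(
    t: np.ndarray, onset: float, duration: float, amplitude: float, rise_time: float
) -> np.ndarray:
    """Deflect-hold-return pulse: sigmoidal edges, plateau ``amplitude``.

    The logistic scale is rise_time/6 so ~95% of the transition happens
    within one rise time.
    """
    scale = rise_time / 6.0
    up = expit((t - onset) / scale)
    down = expit((t - (onset + duration)) / scale)
    return amplitude * (up - down)


def _blink_spike(
    t: np.ndarray, onset: float, duration: float, amplitude: float
) -> np.ndarray:
    """Biphasic blink artifact: dominant positive lobe, small undershoot.

    Peak equals ``amplitude``; the full width at half maximum is about
    0.4 * duration, well under the saccade hold time, which is what lets
    the rule classifier separate blinks from large upward saccades.
    """
    center = onset + 0.35 * duration
    sigma = duration / 6.0
    main = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    under_center = onset + 0.75 * duration
    under = np.exp(-0.5 * ((t - under_center) / (duration / 5.0)) ** 2)
    return amplitude * main - 0.25 * amplitude * under


def _event_channel_amplitude(event: GazeEvent, config: SimulatorConfig) -> tuple[int, float]:
    """(channel index, signed plateau amplitude) for a saccadic event."""
    angle = abs(event.angle) if event.angle is not None else 0.0
    amp = config.sensitivity * angle
    if event.label == "R":
        return 0, amp
    if event.label == "L":
        return 0, -amp
    if event.label == "U":
        return 1, amp
    if event.label == "D":
        return 1, -amp
    raise ValueError(f"not a saccadic class: {event.label}")


def _validate_script(script: GazeScript, config: SimulatorConfig) -> None:
    max_vert_saccade = 0.0
    for e in script:
        if e.label in ("U", "D", "L", "R"):
            if e.angle is None:
                raise ValidationError(f"{e.label} event at {e.onset}s needs an angle")
            amp = config.sensitivity * abs(e.angle)
            if amp > MAX_AMPLITUDE_UV:
                raise ValidationError(
                    f"saccade to {e.angle} deg gives {amp:.0f} uV, above the "
                    f"{MAX_AMPLITUDE_UV:.0f} uV physiological ceiling"
                )
            if e.label in ("U", "D"):
                max_vert_saccade = max(max_vert_saccade, amp)
    has_blink = any(e.label == "B" for e in script)
    if has_blink and config.blink_amplitude <= max_vert_saccade:
        raise ValidationError(
            f"blink_amplitude ({config.blink_amplitude} uV) must exceed the "
            f"largest scripted vertical saccade ({max_vert_saccade} uV)"
        )


def _nuisance(
    n: int, config: SimulatorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Drift + powerline + white noise for both channels, shape (2, n)."""
    t = np.arange(n) / config.sample_rate
    out = np.zeros((2, n))
    for ch in range(2):
        if config.drift_amplitude > 0:
            phase = rng.uniform(0, 2 * math.pi)
            out[ch] += config.drift_amplitude * np.sin(
                2 * math.pi * t / config.drift_period + phase
            )
        if config.powerline_amplitude > 0:
            phase = rng.uniform(0, 2 * math.pi)
            out[ch] += config.powerline_amplitude * np.sin(
                2 * math.pi * config.powerline_freq * t + phase
            )
    if config.noise_sigma > 0:
        out += rng.normal(0.0, config.noise_sigma, size=(2, n))
    return out


def synthesize_recording(
    script: GazeScript,
    config: SimulatorConfig,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EOGRecording, LabelTrack]:
    """Render a gaze script into a two-channel recording plus ground truth.

    Deterministic for a fixed config seed. ``duration`` defaults to the
    script end plus a 0.5 s tail. Pass an explicit ``rng`` to draw the
    nuisance terms from an external stream (used by the batch
    generators); otherwise a fresh generator is seeded from the config.
    """
    _validate_script(script, config)
    if duration is None:
        duration = script.end + 0.5
    n = int(round(duration * config.sample_rate))
    if n <= 0:
        raise ValidationError(f"requested duration {duration}s yields no samples")
    t = np.arange(n) / config.sample_rate
    clean = np.zeros((2, n))
    for e in script:
        if e.label == "N":
            continue
        if e.label == "B":
            clean[1] += _blink_spike(t, e.onset, e.duration, config.blink_amplitude)
        else:
            ch, amp = _event_channel_amplitude(e, config)
            clean[ch] += _saccade_pulse(
                t, e.onset, e.duration, amp, config.saccade_rise_time
            )
    if rng is None:
        rng = config.rng()
    samples = clean + _nuisance(n, config, rng)
    rec = EOGRecording(samples, config.sample_rate)
    track = LabelTrack(script.events, rec.duration)
    return rec, track


def _epoch_script(
    label: str,
    angle: float | None,
    window_s: float,
    event_duration: float,
    blink_duration: float,
) -> GazeScript:
    """Script for a single benchmark epoch: one event inside the window.

    The event starts at 30% of the window so the pulse (deflect, hold,
    return) sits fully inside it with baseline on both sides.
    """
    onset = 0.3 * window_s
    if label == "N":
        return GazeScript([GazeEvent("N", onset, event_duration)])
    if label == "B":
        return GazeScript([GazeEvent("B", onset, blink_duration)])
    return GazeScript([GazeEvent(label, onset, event_duration, angle)])


def make_benchmark_dataset(
    n_per_class: int,
    config: SimulatorConfig,
    angle_range: tuple[float, float] = (10.0, 30.0),
    window_s: float = 1.0,
    event_duration: float = 0.4,
) -> EpochSet:
    """Class-balanced labeled one-second epochs for classifier benchmarks.

    Produces ``6 * n_per_class`` epochs, ``n_per_class`` of each class in
    (D, L, N, R, U, B) order interleaved round-robin, with saccade angles
    drawn uniformly from ``angle_range`` degrees. All randomness (angles,
    drift/powerline phases, noise) flows from the config seed.
    """
    if n_per_class < 1:
        raise ValidationError(f"n_per_class must be >= 1, got {n_per_class}")
    lo, hi = angle_range
    if not (0 < lo <= hi):
        raise ValidationError(f"invalid angle range {angle_range}")
    if config.sensitivity * hi > MAX_AMPLITUDE_UV:
        raise ValidationError(
            f"angle range {angle_range} exceeds the {MAX_AMPLITUDE_UV:.0f} uV ceiling"
        )
    rng = config.rng()
    w = int(round(window_s * config.sample_rate))
    classes = ("D", "L", "N", "R", "U", "B")
    n_total = 6 * n_per_class
    X = np.empty((n_total, 2, w))
    y = np.empty(n_total, dtype=object)
    angles = np.full(n_total, np.nan)
    i = 0
    for _ in range(n_per_class):
        for label in classes:
            angle = float(rng.uniform(lo, hi)) if label in "DLRU" else None
            script = _epoch_script(
                label, angle, window_s, event_duration, config.blink_duration
            )
            rec, _ = synthesize_recording(
                script, config, duration=window_s, rng=rng
            )
            X[i] = rec.samples[:, :w]
            y[i] = label
            angles[i] = angle if angle is not None else np.nan
            i += 1
    return EpochSet(X, y, config.sample_rate, angles)


def make_tracking_recording(
    angles: list[float],
    config: SimulatorConfig,
    fixation_s: float = 1.0,
    gap_s: float = 0.6,
    rng: np.random.Generator | None = None,
) -> tuple[EOGRecording, LabelTrack]:
    """Target-tracking protocol: horizontal fixation plateaus at each angle.

    Emulates tracing marked targets at known gaze angles: for each signed
    angle the horizontal channel steps to ``sensitivity * angle`` and
    holds for ``fixation_s``, returning to center between targets. The
    returned labels carry the signed angle, ready for the sensitivity
    regression. Angle 0 produces a labeled null span.
    """
    events = []
    t = gap_s
    for a in angles:
        if abs(a) > 60.0:
            raise ValidationError(f"tracking angle {a} deg outside +/-60 deg")
        if a == 0:
            events.append(GazeEvent("N", t, fixation_s))
        else:
            label = "R" if a > 0 else "L"
            events.append(GazeEvent(label, t, fixation_s, angle=float(a)))
        t += fixation_s + gap_s
    script = GazeScript(events)
    return synthesize_recording(script, config, duration=t + 0.2, rng=rng)


def make_snr_recording(
    config: SimulatorConfig,
    n_segments: int = 5,
    segment_s: float = 5.0,
    angle: float = 25.0,
    gazes_per_segment: int = 6,
    gaze_duration: float = 0.45,
) -> tuple[EOGRecording, LabelTrack]:
    """The SNR protocol: left/right gazes at regular intervals per segment.

    Each ``segment_s`` segment holds ``gazes_per_segment`` alternating
    L/R gazes (three left and three right by default) on a regular grid,
    mirroring the left-right gaze recording used to score electrode SNR.
    """
    if n_segments < 1 or gazes_per_segment < 1:
        raise ValidationError("need at least one segment and one gaze")
    events = []
    spacing = segment_s / (gazes_per_segment + 1)
    if gaze_duration >= spacing:
        raise ValidationError(
            f"gaze_duration {gaze_duration}s does not fit the "
            f"{spacing:.2f}s grid of {gazes_per_segment} gazes per segment"
        )
    for seg in range(n_segments):
        t0 = seg * segment_s
        for i in range(gazes_per_segment):
            label = "L" if i % 2 == 0 else "R"
            onset = t0 + spacing * (i + 0.5)
            events.append(GazeEvent(label, onset, gaze_duration, angle=angle))
    script = GazeScript(events)
    return synthesize_recording(
        script, config, duration=n_segments * segment_s
    )
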