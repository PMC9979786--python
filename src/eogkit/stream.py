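"""Sliding-window real-time classification and gaze-to-command mapping.

A rolling one-second window steps through the sample stream; each step
runs the preprocessing chain and a fitted classifier on the window.
Debouncing turns window-level labels into discrete gaze events:

* a non-null label is emitted only after ``votes_required`` consecutive
  agreeing windows (blink excepted: a blink fires on its first window,
  because blink maps to the emergency STOP);
* after an emission the detector enters a refractory period and is
  re-armed only once a window classifies as null again, so one long
  saccade cannot fire twice;
* null windows emit nothing.

Commands for the two-wheeled vehicle: U -> FORWARD, D -> REVERSE,
L -> CCW (counter-clockwise turn), R -> CW, B -> STOP; null maps to no
command. The bundled track demo replays a seven-maneuver gaze script
(forward, turn-and-forward, ... reverse-to-park) end to end through the
simulator, the streaming classifier and the command map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessPipeline
from .rule import RuleClassifier
from .simulate import SimulatorConfig, make_benchmark_dataset, synthesize_recording
from .types import CLASSES, EOGRecording, GazeEvent, GazeScript, ValidationError

#: The five device commands of the RC-car demo.
COMMANDS = ("FORWARD", "REVERSE", "STOP", "CCW", "CW")

_DEFAULT_MAP = {"U": "FORWARD", "D": "REVERSE", "B": "STOP", "L": "CCW", "R": "CW", "N": None}


@dataclass(frozen=True)
class CommandMap:
    """Total mapping from the six gaze classes to device commands.

    Exactly five distinct commands; blink must map to STOP (emergency
    stop); null maps to no command.
    """

    mapping: dict = field(default_factory=lambda: dict(_DEFAULT_MAP))

    def __post_init__(self) -> None:
        if set(self.mapping) != CLASSES:
            raise ValidationError(
                f"mapping must cover exactly the classes {sorted(CLASSES)}; "
                f"got {sorted(self.mapping)}"
            )
        if self.mapping["B"] != "STOP":
            raise ValidationError("blink (B) must map to STOP")
        if self.mapping["N"] is not None:
            raise ValidationError("null (N) must map to no command")
        cmds = [v for k, v in self.mapping.items() if k != "N"]
        if len(set(cmds)) != 5:
            raise ValidationError(f"expected 5 distinct device commands, got {sorted(set(cmds))}")

    def __getitem__(self, label: str) -> str | None:
        if label not in self.mapping:
            raise ValidationError(f"unknown class {label!r}")
        return self.mapping[label]


@dataclass(frozen=True)
class StreamConfig:
    """Sliding-window and debounce settings (seconds / window counts)."""

    window_s: float = 1.0
    step_s: float = 0.1
    votes_required: int = 2
    refractory_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.window_s:
            raise ValidationError(
                f"need 0 < step_s <= window_s; got step={self.step_s}, "
                f"window={self.window_s}"
            )
        if self.votes_required < 1:
            raise ValidationError("votes_required must be >= 1")
        if self.refractory_s < 0:
            raise ValidationError("refractory_s must be >= 0")


def stream_classify(
    source,
    model,
    cfg: StreamConfig | None = None,
    sample_rate: float = 250.0,
    pipeline: PreprocessPipeline | None = None,
) -> list[tuple[float, str]]:
    """Run the sliding-window detector over a recording or sample stream.

    ``source`` is an :class:`EOGRecording` or an iterable of two-channel
    samples at ``sample_rate``. Returns ``(time, class)`` events, where
    time is the end of the window that completed the vote. Worst-case
    detection latency is ``window_s + votes_required * step_s`` after
    event onset; a blink is emitted within one window.
    """
    cfg = cfg or StreamConfig()
    pipeline = pipeline or PreprocessPipeline()
    if isinstance(source, EOGRecording):
        if source.sample_rate != sample_rate:
            raise ValidationError(
                f"stream sample rate {source.sample_rate} Hz does not match the "
                f"expected {sample_rate} Hz"
            )
        samples = source.samples
    else:
        arr = np.asarray(list(source), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError("sample stream must yield two-channel samples")
        samples = arr.T
    w = int(round(cfg.window_s * sample_rate))
    step = max(1, int(round(cfg.step_s * sample_rate)))
    n = samples.shape[1]
    events: list[tuple[float, str]] = []
    streak_label: str | None = None
    streak = 0
    refractory_until = -np.inf
    armed = True
    for stop in range(w, n + 1, step):
        t = stop / sample_rate
        window = samples[:, stop - w : stop]
        label = str(model.predict(pipeline.process_array(window, sample_rate)[None])[0])
        if label == "N":
            streak_label, streak = None, 0
            if t >= refractory_until:
                armed = True
            continue
        if label == streak_label:
            streak += 1
        else:
            streak_label, streak = label, 1
        can_fire = armed and t >= refractory_until
        if can_fire and (label == "B" or streak >= cfg.votes_required):
            events.append((t, label))
            refractory_until = t + cfg.refractory_s
            armed = False
            streak_label, streak = None, 0
    return events


def map_to_commands(
    events, cmap: CommandMap | None = None
) -> list[tuple[float, str]]:
    """Translate (time, class) events into (time, command) records.

    Null events produce nothing; STOP (from a blink) passes straight
    through like every other command — the stream layer already gives
    blinks their fast path.
    """
    cmap = cmap or CommandMap()
    out = []
    for item in events:
        t, label = item if isinstance(item, tuple) else (None, item)
        cmd = cmap[label]
        if cmd is not None:
            out.append((t, cmd))
    return out


# ---------------------------------------------------------------------------
# track demo: seven consecutive maneuvers from start to parking

#: Gaze classes per numbered maneuver of the demo track:
#: (1) go forward, (2) CCW turn + forward, (3) CW turn, (4) forward,
#: (5) CW turn + forward, (6) CW turn, (7) reverse to park.
TRACK_MANEUVERS: tuple[tuple[str, ...], ...] = (
    ("U",),
    ("L", "U"),
    ("R",),
    ("U",),
    ("R", "U"),
    ("R",),
    ("D",),
)

EXPECTED_TRACK_COMMANDS: tuple[tuple[str, ...], ...] = (
    ("FORWARD",),
    ("CCW", "FORWARD"),
    ("CW",),
    ("FORWARD",),
    ("CW", "FORWARD"),
    ("CW",),
    ("REVERSE",),
)


def build_track_script(
    angle: float = 25.0,
    event_duration: float = 0.4,
    intra_gap: float = 1.6,
    inter_gap: float = 3.0,
    start: float = 1.0,
) -> tuple[GazeScript, list[tuple[float, float]]]:
    """The seven-maneuver demo script plus per-maneuver time windows."""
    events = []
    windows = []
    t = start
    for group in TRACK_MANEUVERS:
        g0 = t - 0.5
        for label in group:
            angle_arg = angle if label in "UDLR" else None
            events.append(GazeEvent(label, t, event_duration, angle_arg))
            t += intra_gap
        windows.append((g0, t - intra_gap + event_duration + 1.0))
        t += inter_gap - intra_gap
    return GazeScript(events), windows


@dataclass(frozen=True)
class DemoResult:
    """Outcome of the headless track replay."""

    groups: tuple[tuple[str, ...], ...]
    expected: tuple[tuple[str, ...], ...] = EXPECTED_TRACK_COMMANDS
    commands: tuple[tuple[float, str], ...] = ()

    @property
    def passed(self) -> bool:
        return self.groups == self.expected


def default_rule_model(config: SimulatorConfig, n_per_class: int = 8) -> RuleClassifier:
    """Rule classifier calibrated on a small benchmark from ``config``."""
    epochs = make_benchmark_dataset(n_per_class, config)
    processed = PreprocessPipeline().process_epochs(epochs)
    return RuleClassifier().fit(processed)


def run_track_demo(
    model=None,
    cfg: StreamConfig | None = None,
    sim_config: SimulatorConfig | None = None,
    noise: bool = False,
) -> DemoResult:
    """Replay the seven-maneuver track headlessly.

    Synthesizes the demo gaze script (noise-free fixture by default),
    streams it through the classifier and the command map, groups the
    resulting commands by maneuver window, and compares against the
    expected seven command groups.
    """
    sim_config = sim_config or SimulatorConfig()
    if not noise:
        sim_config = sim_config.noiseless()
    if model is None:
        model = default_rule_model(sim_config)
    cfg = cfg or StreamConfig()
    script, windows = build_track_script()
    rec, _ = synthesize_recording(script, sim_config, duration=script.end + 2.0)
    events = stream_classify(rec, model, cfg, sample_rate=sim_config.sample_rate)
    commands = map_to_commands(events)
    groups = []
    for lo, hi in windows:
        groups.append(tuple(cmd for t, cmd in commands if lo <= t < hi))
    return DemoResult(groups=tuple(groups), commands=tuple(commands))
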