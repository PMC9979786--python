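"""Core containers: recordings, gaze events, label tracks and epoch sets.

Conventions used throughout the package:

* channel 1 (index 0) is the horizontal EOG, channel 2 (index 1) the
  vertical EOG;
* positive channel-1 voltage means rightward gaze, positive channel-2
  voltage means upward gaze; a blink is a large positive biphasic spike
  on the vertical channel;
* amplitudes are microvolts, times are seconds;
* the six gaze classes are D, L, N, R, U, B and every axis ordered by
  class (confusion matrices, tie-breaks, one-hot encodings) uses exactly
  that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

#: Fixed class order for confusion matrices, tie-breaks and one-hot codes.
CLASS_ORDER: tuple[str, ...] = ("D", "L", "N", "R", "U", "B")
CLASSES: frozenset[str] = frozenset(CLASS_ORDER)

#: Classes whose events deflect the horizontal (index 0) channel.
HORIZONTAL_CLASSES = frozenset({"L", "R"})
#: Classes whose events deflect the vertical (index 1) channel.
VERTICAL_CLASSES = frozenset({"U", "D", "B"})


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class GazeEvent:
    """A single timed gaze event.

    ``angle`` is the signed gaze angle in degrees for saccadic classes
    (U/D/L/R; the sign is redundant with the label and the stored value
    is the magnitude for U/D/L/R labels, signed for tracking use) and
    ``None`` for blinks and null spans.
    """

    label: str
    onset: float
    duration: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValidationError(
                f"unknown class label {self.label!r}; expected one of {sorted(CLASSES)}"
            )
        if not self.duration > 0:
            raise ValidationError(f"event duration must be > 0, got {self.duration}")
        if self.label in ("B", "N") and self.angle is not None:
            raise ValidationError(f"{self.label} events carry no gaze angle")

    @property
    def end(self) -> float:
        return self.onset + self.duration


def _check_events(events: Sequence[GazeEvent]) -> None:
    """Shared invariant: onsets strictly increasing, events non-overlapping."""
    for prev, cur in zip(events, events[1:]):
        if not cur.onset > prev.onset:
            raise ValidationError(
                f"event onsets must be strictly increasing: {cur.onset} after {prev.onset}"
            )
        if cur.onset < prev.end:
            raise ValidationError(
                f"events overlap: [{prev.onset}, {prev.end}) and "
                f"[{cur.onset}, {cur.end})"
            )


@dataclass(frozen=True)
class GazeScript:
    """An ordered, non-overlapping sequence of gaze events to simulate."""

    events: tuple[GazeEvent, ...]

    def __init__(self, events: Iterable[GazeEvent]):
        object.__setattr__(self, "events", tuple(events))
        _check_events(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[GazeEvent]:
        return iter(self.events)

    @property
    def end(self) -> float:
        return max((e.end for e in self.events), default=0.0)


@dataclass(frozen=True)
class EOGRecording:
    """A uniformly sampled two-channel EOG recording in microvolts.

    ``samples`` has shape ``(2, n)``: row 0 is the horizontal channel,
    row 1 the vertical channel.
    """

    samples: np.ndarray
    sample_rate: float
    channel_roles: tuple[str, str] = ("horizontal", "vertical")

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2 or samples.shape[0] != 2:
            raise ValidationError(
                f"samples must have shape (2, n); got {samples.shape}"
            )
        if not self.sample_rate > 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if not np.isfinite(samples).all():
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def horizontal(self) -> np.ndarray:
        return self.samples[0]

    @property
    def vertical(self) -> np.ndarray:
        return self.samples[1]

    def with_samples(self, samples: np.ndarray) -> "EOGRecording":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class LabelTrack:
    """Timed gaze-event labels aligned to a recording.

    Events must lie within ``[0, duration]`` of the recording they
    annotate. Angles are retained when known (simulator ground truth)
    because the sensitivity regression consumes them.
    """

    events: tuple[GazeEvent, ...]
    duration: float

    def __init__(self, events: Iterable[GazeEvent], duration: float):
        object.__setattr__(self, "events", tuple(events))
        object.__setattr__(self, "duration", float(duration))
        _check_events(self.events)
        for e in self.events:
            if e.onset < 0 or e.end > self.duration + 1e-9:
                raise ValidationError(
                    f"event [{e.onset}, {e.end}) outside recording of "
                    f"duration {self.duration}"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[GazeEvent]:
        return iter(self.events)

    def non_null(self) -> tuple[GazeEvent, ...]:
        return tuple(e for e in self.events if e.label != "N")


@dataclass
class EpochSet:
    """A batch of fixed-length labeled epochs.

    ``X`` has shape ``(n, 2, w)`` (epochs x channels x samples), ``y`` is
    an array of class labels, ``angles`` the per-epoch gaze angle where
    known (NaN otherwise).
    """

    X: np.ndarray
    y: np.ndarray
    sample_rate: float
    angles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 3 or self.X.shape[1] != 2:
            raise ValidationError(f"X must have shape (n, 2, w); got {self.X.shape}")
        if len(self.y) != len(self.X):
            raise ValidationError("X and y lengths differ")
        bad = sorted(set(self.y) - CLASSES)
        if bad:
            raise ValidationError(f"unknown class labels in y: {bad}")
        if self.angles is None:
            self.angles = np.full(len(self.X), np.nan)
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.angles) != len(self.X):
            raise ValidationError("angles length differs from X")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def window_samples(self) -> int:
        return self.X.shape[2]

    def subset(self, idx: np.ndarray | Sequence[int]) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(self.X[idx], self.y[idx], self.sample_rate, self.angles[idx])

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.y == c)) for c in CLASS_ORDER}

    @staticmethod
    def concatenate(parts: Sequence["EpochSet"]) -> "EpochSet":
        if not parts:
            raise ValueError("cannot concatenate an empty list of epoch sets")
        sr = parts[0].sample_rate
        if any(p.sample_rate != sr for p in parts):
            raise ValidationError("epoch sets have differing sample rates")
        return EpochSet(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            sr,
            np.concatenate([p.angles for p in parts]),
        )
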