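"""Readers and writers for recordings, label tracks, epoch containers,
thresholds and reports.

Plain-text formats:

* recording CSV — header ``time_s,ch1_uV,ch2_uV``, one row per sample;
  the sample rate is inferred from the time column, which must be
  uniform and monotone;
* label CSV — header ``onset_s,duration_s,label`` plus an optional
  ``angle_deg`` column written when any event carries an angle;
* epoch container — numpy ``.npz`` with arrays ``X`` (n, 2, w), ``y``
  (labels), ``angles`` and scalar ``sample_rate``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CLASSES, EOGRecording, EpochSet, GazeEvent, LabelTrack, ValidationError

RECORDING_COLUMNS = ("time_s", "ch1_uV", "ch2_uV")
LABEL_COLUMNS = ("onset_s", "duration_s", "label")


class HeaderError(ValidationError):
    """A CSV file does not carry the documented columns."""


class NonMonotoneTimeError(ValidationError):
    """The time column of a recording is not strictly increasing."""


class NonUniformSamplingError(ValidationError):
    """The time column of a recording is not uniformly sampled."""


def write_recording(rec: EOGRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": rec.times,
            "ch1_uV": rec.horizontal,
            "ch2_uV": rec.vertical,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_recording(path: str | Path, time_jitter_s: float = 1e-6) -> EOGRecording:
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise HeaderError(
            f"{path}: missing recording column(s) {missing}; expected header "
            f"{','.join(RECORDING_COLUMNS)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValidationError(f"{path}: a recording needs at least 2 samples")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise NonMonotoneTimeError(f"{path}: time column is not strictly increasing")
    if (np.abs(dt - np.median(dt)) > time_jitter_s).any():
        raise NonUniformSamplingError(
            f"{path}: sampling is not uniform within {time_jitter_s} s"
        )
    sample_rate = 1.0 / float(np.median(dt))
    samples = np.vstack([df["ch1_uV"].to_numpy(float), df["ch2_uV"].to_numpy(float)])
    return EOGRecording(samples, sample_rate)


def write_labels(track: LabelTrack, path: str | Path) -> None:
    rows = []
    has_angle = any(e.angle is not None for e in track)
    for e in track:
        row = {"onset_s": e.onset, "duration_s": e.duration, "label": e.label}
        if has_angle:
            row["angle_deg"] = e.angle if e.angle is not None else ""
        rows.append(row)
    cols = list(LABEL_COLUMNS) + (["angle_deg"] if has_angle else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.8g")


def read_labels(path: str | Path, duration: float | None = None) -> LabelTrack:
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise HeaderError(
            f"{path}: missing label column(s) {missing}; expected header "
            f"{','.join(LABEL_COLUMNS)}"
        )
    events = []
    for _, row in df.iterrows():
        label = str(row["label"]).strip()
        if label not in CLASSES:
            raise ValidationError(f"{path}: unknown label {label!r}")
        angle = None
        if "angle_deg" in df.columns and not pd.isna(row["angle_deg"]):
            val = row["angle_deg"]
            if not (isinstance(val, str) and not val.strip()):
                angle = float(val)
        if label in ("B", "N"):
            angle = None
        events.append(
            GazeEvent(label, float(row["onset_s"]), float(row["duration_s"]), angle)
        )
    events.sort(key=lambda e: e.onset)
    if duration is None:
        duration = max((e.end for e in events), default=0.0)
    return LabelTrack(events, duration)


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    np.savez(
        path,
        X=epochs.X,
        y=np.array([str(v) for v in epochs.y]),
        angles=epochs.angles,
        sample_rate=np.array(epochs.sample_rate),
    )


def load_epochs(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as data:
        return EpochSet(
            data["X"],
            data["y"].astype(object),
            float(data["sample_rate"]),
            data["angles"],
        )


def write_predictions(times_or_index, labels, path: str | Path) -> None:
    pd.DataFrame({"index": times_or_index, "label": list(labels)}).to_csv(
        path, index=False
    )


def write_command_log(commands, path: str | Path) -> None:
    pd.DataFrame(commands, columns=["time_s", "command"]).to_csv(
        path, index=False, float_format="%.4f"
    )


def infer_sample_rate(times: np.ndarray) -> float:
    dt = np.diff(np.asarray(times, dtype=float))
    if len(dt) == 0 or (dt <= 0).any():
        raise NonMonotoneTimeError("cannot infer a sample rate")
    return 1.0 / float(np.median(dt))
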