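"""Evaluation: stratified splitting, confusion matrices, SNR, sensitivity.

SNR follows the rms-ratio convention used for electrode comparisons,

    SNR (dB) = 10 * log10(rms_signal / rms_noise),

computed per recorded segment (event-span samples vs null-span samples
after per-segment mean removal) and summarized as mean +/- standard
error over segments.

Gaze sensitivity is the slope, in microvolts per degree, of the
ordinary least-squares regression of fixation-plateau amplitude on
signed gaze angle, mirroring the marked-target tracking protocol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from scipy import signal as _signal

from .types import CLASS_ORDER, EOGRecording, EpochSet, LabelTrack, ValidationError


def split_train_test(
    epochs: EpochSet, train_fraction: float = 0.75, seed: int = 0
) -> tuple[EpochSet, EpochSet]:
    """Stratified shuffle split; reproducible under ``seed``.

    The total training size is ``round(train_fraction * N)``; per-class
    quotas are apportioned by the largest-remainder method (ties broken
    in fixed class order), so a balanced 1200-epoch set at 0.75 yields
    exactly 150 train / 50 test epochs per class. Classes with fewer
    than 2 members cannot be split and raise.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    y = epochs.y
    present = [c for c in CLASS_ORDER if np.any(y == c)]
    small = [c for c in present if np.sum(y == c) < 2]
    if small:
        raise ValidationError(f"classes with fewer than 2 epochs cannot be split: {small}")
    n_total = len(epochs)
    target_train = int(round(train_fraction * n_total))
    counts = {c: int(np.sum(y == c)) for c in present}
    quotas = {c: train_fraction * counts[c] for c in present}
    floors = {c: math.floor(quotas[c]) for c in present}
    # every class keeps at least one epoch on each side
    for c in present:
        floors[c] = min(max(floors[c], 1), counts[c] - 1)
    remaining = target_train - sum(floors.values())
    order = sorted(
        present, key=lambda c: (-(quotas[c] - math.floor(quotas[c])), CLASS_ORDER.index(c))
    )
    take = dict(floors)
    i = 0
    while remaining > 0 and i < 10 * len(present):
        c = order[i % len(present)]
        if take[c] < counts[c] - 1:
            take[c] += 1
            remaining -= 1
        i += 1
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in present:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        train_idx.extend(idx[: take[c]])
        test_idx.extend(idx[take[c] :])
    return epochs.subset(np.sort(train_idx)), epochs.subset(np.sort(test_idx))


@dataclass(frozen=True)
class ConfusionMatrix:
    """6x6 counts indexed (true, predicted) in class order (D,L,N,R,U,B)."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ValidationError(f"counts must be {k}x{k}; got {counts.shape}")
        if (counts < 0).any():
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total if self.total else float("nan")

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for i, c in enumerate(self.class_order):
            row = self.counts[i].sum()
            out[c] = float(self.counts[i, i] / row) if row else float("nan")
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_order), columns=list(self.class_order)
        )

    def to_json_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "counts": self.counts.tolist(),
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")
        else:
            self.to_dataframe().to_csv(path)


def confusion_and_accuracy(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally a confusion matrix over the six-class alphabet."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if len(t) != len(p):
        raise ValidationError(
            f"label sequences differ in length: {len(t)} vs {len(p)}"
        )
    index = {c: i for i, c in enumerate(CLASS_ORDER)}
    counts = np.zeros((6, 6), dtype=int)
    for ti, pi in zip(t, p):
        if ti not in index:
            raise ValidationError(f"true label {ti!r} outside the class alphabet")
        if pi not in index:
            raise ValidationError(f"predicted label {pi!r} outside the class alphabet")
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class SNRReport:
    """Per-segment rms values and the mean +/- standard-error summary."""

    rms_signal: float
    rms_noise: float
    snr_db: float
    per_segment_db: tuple[float, ...]
    stderr_db: float

    def to_json_dict(self) -> dict:
        return {
            "rms_signal_uv": self.rms_signal,
            "rms_noise_uv": self.rms_noise,
            "snr_db_mean": self.snr_db,
            "snr_db_stderr": self.stderr_db,
            "per_segment_db": list(self.per_segment_db),
        }


def _event_mask(
    labels: LabelTrack, n: int, sample_rate: float, pad_s: float = 0.0
) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    pad = int(round(pad_s * sample_rate))
    for e in labels.non_null():
        a = int(round(e.onset * sample_rate)) - pad
        b = int(round(e.end * sample_rate)) + pad
        mask[max(a, 0) : min(b, n)] = True
    return mask


def snr_analysis(
    rec: EOGRecording,
    labels: LabelTrack,
    segment_s: float = 5.0,
    n_segments: int = 5,
    channel: int = 0,
    stage: str = "detrend",
    guard_s: float = 0.1,
) -> SNRReport:
    """Segmented rms-ratio SNR of one channel.

    The recording is cut into ``n_segments`` consecutive segments of
    ``segment_s``. Per segment the channel is linearly detrended
    (``stage="detrend"``, default) or taken raw (``stage="raw"``), the
    segment mean is removed, and

        snr_db = 10 * log10(rms over event samples / rms over null samples)

    using the label track to separate event spans from null spans. Null
    samples closer than ``guard_s`` to an event are counted in neither
    rms, so saccade rise/return edges straddling an event boundary do
    not contaminate the noise estimate. The report carries each
    segment's value and the mean +/- standard error
    (sample SD / sqrt(n_segments)).
    """
    if stage not in ("detrend", "raw"):
        raise ValidationError(f"stage must be 'detrend' or 'raw', got {stage!r}")
    seg_n = int(round(segment_s * rec.sample_rate))
    need = n_segments * seg_n
    if rec.n_samples < need:
        raise ValidationError(
            f"recording has {rec.n_samples} samples; {need} required for "
            f"{n_segments} x {segment_s}s segments"
        )
    mask = _event_mask(labels, rec.n_samples, rec.sample_rate)
    guarded = _event_mask(labels, rec.n_samples, rec.sample_rate, pad_s=guard_s)
    snrs, rss, rns = [], [], []
    for seg in range(n_segments):
        sl = slice(seg * seg_n, (seg + 1) * seg_n)
        x = rec.samples[channel, sl].astype(float)
        m = mask[sl]
        null = ~guarded[sl]
        if not m.any() or not null.any():
            raise ValidationError(
                f"segment {seg} lacks event or null samples; cannot form the rms ratio"
            )
        if stage == "detrend":
            # fit the linear trend on null samples only: fitting through the
            # large alternating event pulses would tilt the baseline instead
            # of removing drift
            t = np.arange(len(x), dtype=float)
            coef = np.polyfit(t[null], x[null], 1)
            x = x - np.polyval(coef, t)
        x = x - x.mean()
        rms_signal = float(np.sqrt(np.mean(x[m] ** 2)))
        rms_noise = float(np.sqrt(np.mean(x[null] ** 2)))
        if rms_signal <= 0 or rms_noise <= 0:
            raise ValidationError(f"segment {seg} has zero rms; SNR undefined")
        snrs.append(10.0 * math.log10(rms_signal / rms_noise))
        rss.append(rms_signal)
        rns.append(rms_noise)
    snrs_arr = np.array(snrs)
    stderr = float(snrs_arr.std(ddof=1) / math.sqrt(n_segments)) if n_segments > 1 else 0.0
    return SNRReport(
        rms_signal=float(np.mean(rss)),
        rms_noise=float(np.mean(rns)),
        snr_db=float(snrs_arr.mean()),
        per_segment_db=tuple(snrs),
        stderr_db=stderr,
    )


@dataclass(frozen=True)
class SensitivityFit:
    """OLS fit of plateau amplitude (uV) against signed gaze angle (deg)."""

    slope: float
    intercept: float
    slope_stderr: float
    per_angle_amplitude: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "slope_uv_per_deg": self.slope,
            "intercept_uv": self.intercept,
            "slope_stderr": self.slope_stderr,
            "per_angle_amplitude_uv": {str(k): v for k, v in self.per_angle_amplitude.items()},
        }


def sensitivity_fit(
    rec: EOGRecording,
    labels: LabelTrack,
    channel: int = 0,
    plateau_fraction: float = 0.6,
    baseline_guard_s: float = 0.1,
) -> SensitivityFit:
    """Regress fixation-plateau amplitude on signed gaze angle.

    For each labeled event carrying an angle, the plateau amplitude is
    the mean of the central ``plateau_fraction`` of the event span on the
    chosen channel, minus a local pre-onset baseline (the 0.3 s ending
    ``baseline_guard_s`` before onset — the guard keeps the saccade's
    sigmoidal rising edge, which is centered on the onset, out of the
    baseline) to cancel slow drift. Requires at least three distinct
    angles.
    """
    pts = []
    signed_angle = {"R": 1.0, "L": -1.0, "U": 1.0, "D": -1.0}
    for e in labels:
        if e.angle is None:
            continue
        a = float(e.angle)
        if e.label in signed_angle:
            a = signed_angle[e.label] * abs(a)
        margin = (1 - plateau_fraction) / 2 * e.duration
        i0 = int(round((e.onset + margin) * rec.sample_rate))
        i1 = int(round((e.end - margin) * rec.sample_rate))
        if i1 <= i0 or i1 > rec.n_samples:
            continue
        plateau = float(np.mean(rec.samples[channel, i0:i1]))
        b1 = int(round((e.onset - baseline_guard_s) * rec.sample_rate))
        b1 = max(0, b1)
        b0 = max(0, b1 - int(round(0.3 * rec.sample_rate)))
        baseline = float(np.mean(rec.samples[channel, b0:b1])) if b1 > b0 else 0.0
        pts.append((a, plateau - baseline))
    angles = np.array([p[0] for p in pts])
    amps = np.array([p[1] for p in pts])
    if len(set(np.round(angles, 9))) < 3:
        raise ValidationError(
            f"sensitivity fit needs >= 3 distinct angles; got {sorted(set(angles))}"
        )
    A = np.vstack([angles, np.ones_like(angles)]).T
    coef, *_ = np.linalg.lstsq(A, amps, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = amps - A @ coef
    dof = max(len(angles) - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((angles - angles.mean()) ** 2))
    stderr = math.sqrt(s2 / sxx) if sxx > 0 else float("nan")
    per_angle: dict[float, float] = {}
    for a in sorted(set(angles)):
        per_angle[float(a)] = float(amps[angles == a].mean())
    return SensitivityFit(slope, intercept, stderr, per_angle)
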