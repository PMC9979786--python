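"""Magnitude-threshold gaze classifier.

The signal-processing route: after the preprocessing chain, each epoch
is scored by its per-channel peak magnitudes against three calibrated
thresholds. The decision procedure:

1. blink — vertical peak at least ``blink_thresh`` AND the peak's
   half-maximum width below ``blink_max_width`` samples (blinks are
   brief biphasic spikes; upward saccades are tall but wide);
2. null — both peak magnitudes below their thresholds (after
   normalizing each channel by its own threshold);
3. otherwise the channel with the larger normalized magnitude wins
   (horizontal wins exact ties), and the sign of that channel's extremum
   picks the direction: channel 1 -/+ -> L/R, channel 2 -/+ -> D/U.

Thresholds are calibrated as midpoints between class-conditional peak
amplitude distributions, so the classifier carries no fixed microvolt
constants and adapts to whatever gain the front end provides.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .types import CLASS_ORDER, EpochSet, ValidationError


@dataclass(frozen=True)
class ThresholdSet:
    """Calibrated decision thresholds, in microvolts (widths in samples)."""

    horiz_thresh: float
    vert_thresh: float
    blink_thresh: float
    blink_max_width: int = 75  # 300 ms at 250 Hz

    def __post_init__(self) -> None:
        if not self.horiz_thresh > 0:
            raise ValidationError(f"horiz_thresh must be > 0, got {self.horiz_thresh}")
        if not 0 < self.vert_thresh < self.blink_thresh:
            raise ValidationError(
                f"need blink_thresh > vert_thresh > 0; got vert={self.vert_thresh}, "
                f"blink={self.blink_thresh}"
            )
        if self.blink_max_width < 1:
            raise ValidationError("blink_max_width must be >= 1 sample")

    def scaled(self, factor: float) -> "ThresholdSet":
        return ThresholdSet(
            self.horiz_thresh * factor,
            self.vert_thresh * factor,
            self.blink_thresh * factor,
            self.blink_max_width,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        lines = [
            f"horiz_thresh = {self.horiz_thresh!r}",
            f"vert_thresh = {self.vert_thresh!r}",
            f"blink_thresh = {self.blink_thresh!r}",
            f"blink_max_width = {self.blink_max_width}",
        ]
        path.write_text("\n".join(lines) + "\n")

    @staticmethod
    def load(path: str | Path) -> "ThresholdSet":
        fields: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = float(value.strip())
        return ThresholdSet(
            horiz_thresh=fields["horiz_thresh"],
            vert_thresh=fields["vert_thresh"],
            blink_thresh=fields["blink_thresh"],
            blink_max_width=int(fields.get("blink_max_width", 75)),
        )


def _peak_abs(x: np.ndarray) -> float:
    return float(np.max(np.abs(x)))


def calibrate_thresholds(
    epochs: EpochSet, blink_max_width_s: float = 0.3
) -> ThresholdSet:
    """Midpoint calibration from labeled (preprocessed) epochs.

    * ``horiz_thresh`` — midway between the largest channel-1 peak of any
      null epoch and the smallest channel-1 peak of any L/R epoch;
    * ``vert_thresh`` — same construction on channel 2 with N vs U/D;
    * ``blink_thresh`` — midway between the largest channel-2 peak of any
      U epoch and the smallest channel-2 peak of any blink epoch.

    Every class must be represented.
    """
    present = set(epochs.y)
    missing = [c for c in CLASS_ORDER if c not in present]
    if missing:
        raise ValidationError(f"calibration needs every class; missing {missing}")

    def peaks(classes: str, channel: int) -> np.ndarray:
        mask = np.isin(epochs.y, list(classes))
        return np.max(np.abs(epochs.X[mask][:, channel, :]), axis=1)

    horiz = (np.max(peaks("N", 0)) + np.min(peaks("LR", 0))) / 2.0
    vert = (np.max(peaks("N", 1)) + np.min(peaks("UD", 1))) / 2.0
    blink = (np.max(peaks("U", 1)) + np.min(peaks("B", 1))) / 2.0
    width = int(round(blink_max_width_s * epochs.sample_rate))
    return ThresholdSet(horiz, vert, blink, width)


def _half_max_width(x: np.ndarray) -> int:
    """Contiguous samples around the absolute peak above half its height."""
    peak_idx = int(np.argmax(np.abs(x)))
    sign = 1.0 if x[peak_idx] >= 0 else -1.0
    y = sign * x
    half = y[peak_idx] / 2.0
    left = peak_idx
    while left > 0 and y[left - 1] >= half:
        left -= 1
    right = peak_idx
    while right < len(y) - 1 and y[right + 1] >= half:
        right += 1
    return right - left + 1


def classify_epoch(epoch: np.ndarray, thresholds: ThresholdSet) -> str:
    """Classify one preprocessed (2, w) epoch into {U, D, L, R, B, N}."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] != 2:
        raise ValidationError(f"epoch must have shape (2, w); got {epoch.shape}")
    if not np.isfinite(epoch).all():
        raise ValidationError("epoch contains non-finite samples")
    ch1, ch2 = epoch
    p1 = _peak_abs(ch1)
    p2 = _peak_abs(ch2)
    if p2 >= thresholds.blink_thresh:
        if _half_max_width(ch2) < thresholds.blink_max_width:
            return "B"
    r1 = p1 / thresholds.horiz_thresh
    r2 = p2 / thresholds.vert_thresh
    if max(r1, r2) < 1.0:
        return "N"
    if r1 >= r2:  # horizontal wins ties
        extremum = ch1[np.argmax(np.abs(ch1))]
        return "R" if extremum >= 0 else "L"
    extremum = ch2[np.argmax(np.abs(ch2))]
    return "U" if extremum >= 0 else "D"


def event_signal(epoch: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Unit-magnitude event channels: sign(ch) where |ch| crosses its
    threshold, 0 elsewhere. Shape (2, w), values in {-1, 0, +1}."""
    epoch = np.asarray(epoch, dtype=float)
    out = np.zeros_like(epoch)
    for ch, thresh in ((0, thresholds.horiz_thresh), (1, thresholds.vert_thresh)):
        mask = np.abs(epoch[ch]) >= thresh
        out[ch, mask] = np.sign(epoch[ch, mask])
    return out


class RuleClassifier:
    """Threshold classifier with the common fit/predict contract.

    ``fit`` calibrates a :class:`ThresholdSet` from labeled preprocessed
    epochs; ``predict`` applies the decision procedure epoch by epoch.
    """

    def __init__(self, thresholds: ThresholdSet | None = None):
        self.thresholds = thresholds

    def fit(self, epochs: EpochSet) -> "RuleClassifier":
        self.thresholds = calibrate_thresholds(epochs)
        return self

    def predict(self, X: np.ndarray | EpochSet) -> np.ndarray:
        if self.thresholds is None:
            raise ValidationError("RuleClassifier is not fitted/calibrated")
        arr = X.X if isinstance(X, EpochSet) else np.asarray(X, dtype=float)
        return np.array(
            [classify_epoch(e, self.thresholds) for e in arr], dtype=object
        )
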