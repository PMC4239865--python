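"""Turn-onset detection by thresholds on vertical-axis angular velocity and angle.

A turn is declared at the first sample where the absolute angular velocity
strictly exceeds ``gyr_thresh`` (gyro criterion) or the absolute
zero-referenced orientation strictly exceeds ``angle_thresh`` (angle
criterion).  Either criterion can be disabled, giving the three detector
variants compared in evaluation: angle-only, gyro-only, combined.

Both a batch form (:func:`detect_onset`, vectorized linear scan) and a
causal streaming form (:class:`StreamingOnsetDetector`) are provided; they
are equivalent by construction and property-tested to agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from turndetect.imu_signals import VerticalAxisSignals

__all__ = [
    "ThresholdPair",
    "DetectionResult",
    "detect_onset",
    "detect_onset_streaming",
    "StreamingOnsetDetector",
    "DEFAULT_SEARCH_START_MS",
]

#: Default start of the monitored range: end of the 1-s baseline window.
DEFAULT_SEARCH_START_MS = 1000.0

CRITERIA = ("angle_only", "gyro_only", "combined")


@dataclass(frozen=True)
class ThresholdPair:
    """Detection thresholds with an enabled-criteria selector.

    ``gyr_thresh`` is in deg/s, ``angle_thresh`` in deg; a disabled
    threshold is ``None``.  ``criterion`` selects which checks run.
    """

    gyr_thresh: float | None
    angle_thresh: float | None
    criterion: str = "combined"

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if self.criterion in ("gyro_only", "combined"):
            if self.gyr_thresh is None or not self.gyr_thresh > 0:
                raise ValueError(f"{self.criterion} requires gyr_thresh > 0")
        elif self.gyr_thresh is not None:
            raise ValueError("angle_only requires gyr_thresh disabled (None)")
        if self.criterion in ("angle_only", "combined"):
            if self.angle_thresh is None or not self.angle_thresh > 0:
                raise ValueError(f"{self.criterion} requires angle_thresh > 0")
        elif self.angle_thresh is not None:
            raise ValueError("gyro_only requires angle_thresh disabled (None)")

    @classmethod
    def combined(cls, gyr_thresh: float, angle_thresh: float) -> "ThresholdPair":
        return cls(gyr_thresh, angle_thresh, "combined")

    @classmethod
    def gyro_only(cls, gyr_thresh: float) -> "ThresholdPair":
        return cls(gyr_thresh, None, "gyro_only")

    @classmethod
    def angle_only(cls, angle_thresh: float) -> "ThresholdPair":
        return cls(None, angle_thresh, "angle_only")

    @property
    def uses_gyro(self) -> bool:
        return self.criterion in ("gyro_only", "combined")

    @property
    def uses_angle(self) -> bool:
        return self.criterion in ("angle_only", "combined")


@dataclass(frozen=True)
class DetectionResult:
    """Whether, when and why a turn was declared in one trial."""

    detected: bool
    onset_ms: float | None = None
    trigger: str | None = None  # "gyro" | "angle" | "both"

    def __post_init__(self) -> None:
        if self.detected:
            if self.onset_ms is None or self.trigger is None:
                raise ValueError("detected results need onset_ms and trigger")
            if self.trigger not in ("gyro", "angle", "both"):
                raise ValueError(f"unknown trigger {self.trigger!r}")
        else:
            if self.onset_ms is not None or self.trigger is not None:
                raise ValueError("undetected results carry no onset_ms/trigger")

    @classmethod
    def none(cls) -> "DetectionResult":
        return cls(detected=False)


def _start_index(signals: VerticalAxisSignals, search_start_ms: float) -> int:
    """First sample index at or after ``search_start_ms``."""
    idx = int(np.ceil(search_start_ms * signals.sample_rate / 1000.0 - 1e-9))
    if idx < 0:
        idx = 0
    if idx >= signals.n_samples:
        raise ValueError(
            f"search_start_ms={search_start_ms} is beyond the series end "
            f"({signals.duration_ms} ms)"
        )
    return idx


def detect_onset(
    signals: VerticalAxisSignals,
    thresholds: ThresholdPair,
    search_start_ms: float = DEFAULT_SEARCH_START_MS,
) -> DetectionResult:
    """Batch turn-onset detection on baseline-zeroed signals.

    Returns the earliest sample at or after ``search_start_ms`` where an
    enabled criterion is strictly exceeded.  ``trigger`` records which
    criterion fired ("both" when both exceed at the same sample).
    """
    start = _start_index(signals, search_start_ms)
    gyro_hit = (
        np.abs(signals.angular_velocity[start:]) > thresholds.gyr_thresh
        if thresholds.uses_gyro
        else None
    )
    angle_hit = (
        np.abs(signals.angle[start:]) > thresholds.angle_thresh
        if thresholds.uses_angle
        else None
    )
    if gyro_hit is None:
        fired = angle_hit
    elif angle_hit is None:
        fired = gyro_hit
    else:
        fired = gyro_hit | angle_hit
    if not fired.any():
        return DetectionResult.none()
    k = int(np.argmax(fired))
    g = bool(gyro_hit[k]) if gyro_hit is not None else False
    a = bool(angle_hit[k]) if angle_hit is not None else False
    trigger = "both" if (g and a) else ("gyro" if g else "angle")
    onset_ms = (start + k) / signals.sample_rate * 1000.0
    return DetectionResult(detected=True, onset_ms=onset_ms, trigger=trigger)


class StreamingOnsetDetector:
    """Causal sample-by-sample onset detector.

    Feed ``(angular_velocity, angle)`` pairs in time order via
    :meth:`update`; once fired the detector latches and ignores further
    input.  Equivalent to :func:`detect_onset` on the completed series.
    """

    def __init__(
        self,
        thresholds: ThresholdPair,
        sample_rate: float = 100.0,
        search_start_ms: float = DEFAULT_SEARCH_START_MS,
    ) -> None:
        if sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.thresholds = thresholds
        self.sample_rate = sample_rate
        self._start_index = int(np.ceil(search_start_ms * sample_rate / 1000.0 - 1e-9))
        self._k = 0
        self._result = DetectionResult.none()

    @property
    def result(self) -> DetectionResult:
        return self._result

    def update(self, angular_velocity: float, angle: float) -> DetectionResult:
        """Consume one sample; returns the current (possibly latched) result."""
        k = self._k
        self._k += 1
        if self._result.detected or k < self._start_index:
            return self._result
        th = self.thresholds
        g = th.uses_gyro and abs(angular_velocity) > th.gyr_thresh
        a = th.uses_angle and abs(angle) > th.angle_thresh
        if g or a:
            trigger = "both" if (g and a) else ("gyro" if g else "angle")
            self._result = DetectionResult(
                detected=True,
                onset_ms=k / self.sample_rate * 1000.0,
                trigger=trigger,
            )
        return self._result


def detect_onset_streaming(
    feed: Iterable[tuple[float, float]],
    thresholds: ThresholdPair,
    sample_rate: float = 100.0,
    search_start_ms: float = DEFAULT_SEARCH_START_MS,
) -> DetectionResult:
    """Run the streaming detector over an in-process feed of (omega, theta)."""
    detector = StreamingOnsetDetector(thresholds, sample_rate, search_start_ms)
    for omega, theta in feed:
        result = detector.update(float(omega), float(theta))
        if result.detected:
            break
    return detector.result
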