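"""Data model for vertical-axis IMU trial recordings and their persistence.

A walking trial is recorded by up to nine body-worn IMUs (head, upper back,
lower back, and thigh/shank/foot on each side).  Because only left/right
turning matters, three channels per IMU are kept: raw vertical-axis angular
velocity (deg/s), fused vertical-axis orientation (deg) and the vertical-axis
magnetometer heading (arbitrary units).  Orientation and heading are only
ever used zero-referenced to the standing phase at the start of the trial
(:func:`baseline_subtract`).

On-disk dialect: one CSV per trial (columns ``t_ms`` then, per location,
``<loc>_gyro_dps``, ``<loc>_angle_deg``, ``<loc>_mag``) with a JSON sidecar
carrying the labels, plus a cohort manifest JSON grouping trial files by
subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorLocation",
    "VerticalAxisSignals",
    "TrialRecording",
    "PATH_LABELS",
    "TrialFormatError",
    "TrialConsistencyError",
    "baseline_subtract",
    "read_trial",
    "write_trial",
    "read_cohort",
    "write_cohort_manifest",
    "path_amplitude",
    "path_direction",
]

#: The seven travel paths of the measurement protocol: continue straight, or
#: turn left/right by 22, 45 or 90 degrees.
PATH_LABELS = (
    "straight",
    "left_22",
    "left_45",
    "left_90",
    "right_22",
    "right_45",
    "right_90",
)

#: Float precision (decimals) guaranteed by the CSV round trip.
CSV_DECIMALS = 6


class TrialFormatError(ValueError):
    """A trial file does not follow the CSV + sidecar-JSON dialect."""


class TrialConsistencyError(ValueError):
    """Trial fields violate an invariant (lengths, labels, onset presence)."""


class SensorLocation(str, Enum):
    """Body placement of one IMU."""

    HEAD = "head"
    UPPER_BACK = "upper_back"
    LOWER_BACK = "lower_back"
    LEFT_THIGH = "left_thigh"
    RIGHT_THIGH = "right_thigh"
    LEFT_SHANK = "left_shank"
    RIGHT_SHANK = "right_shank"
    LEFT_FOOT = "left_foot"
    RIGHT_FOOT = "right_foot"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def path_amplitude(path_label: str) -> int | None:
    """Unsigned turn amplitude in degrees (22/45/90), or None for straight."""
    if path_label == "straight":
        return None
    return int(path_label.split("_")[1])


def path_direction(path_label: str) -> str | None:
    """``left`` or ``right``, or None for a straight path."""
    if path_label == "straight":
        return None
    return path_label.split("_")[0]


def signed_amplitude(path_label: str) -> float:
    """Signed amplitude in degrees; positive = left turn, 0 for straight."""
    amp = path_amplitude(path_label)
    if amp is None:
        return 0.0
    return float(amp) if path_direction(path_label) == "left" else -float(amp)


@dataclass(frozen=True)
class VerticalAxisSignals:
    """The three vertical-axis channels of one IMU over one trial.

    Parameters
    ----------
    angular_velocity:
        Raw gyroscope output around the vertical axis, deg/s.
    angle:
        Fused orientation around the vertical axis, deg, zero-referenced to
        the trial start after :func:`baseline_subtract`.
    mag_heading:
        Magnetometer heading around the vertical axis, arbitrary units,
        likewise zero-referenced.
    sample_rate:
        Sampling frequency in Hz (default 100). Sample ``k`` is at time
        ``k / sample_rate`` seconds, 0-based.
    """

    angular_velocity: np.ndarray
    angle: np.ndarray
    mag_heading: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        for name in ("angular_velocity", "angle", "mag_heading"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = len(self.angular_velocity)
        if n < 1:
            raise TrialConsistencyError("signals must contain at least one sample")
        if len(self.angle) != n or len(self.mag_heading) != n:
            raise TrialConsistencyError(
                f"channel lengths differ: gyro {n}, angle {len(self.angle)}, "
                f"mag {len(self.mag_heading)}"
            )
        if not self.sample_rate > 0:
            raise TrialConsistencyError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.angular_velocity)

    @property
    def duration_ms(self) -> float:
        """Time of the last sample in ms (first sample is at 0 ms)."""
        return (self.n_samples - 1) / self.sample_rate * 1000.0

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate * 1000.0

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest ``t_ms``; raises if outside the series."""
        idx = int(round(t_ms * self.sample_rate / 1000.0))
        if idx < 0 or idx >= self.n_samples:
            raise ValueError(
                f"time {t_ms} ms is outside the series (0..{self.duration_ms} ms)"
            )
        return idx


@dataclass(frozen=True)
class TrialRecording:
    """One labelled walking trial: signals per IMU location plus ground truth.

    ``reference_onset_ms`` is present exactly when the path contains a turn.
    """

    subject_id: str
    trial_id: str
    path_label: str
    signals: Mapping[SensorLocation, VerticalAxisSignals]
    reference_onset_ms: float | None
    walk_start_ms: float

    def __post_init__(self) -> None:
        if self.path_label not in PATH_LABELS:
            raise TrialConsistencyError(f"unknown path_label {self.path_label!r}")
        object.__setattr__(self, "signals", dict(self.signals))
        if not self.signals:
            raise TrialConsistencyError("trial carries no signals")
        is_turn = self.path_label != "straight"
        if is_turn and self.reference_onset_ms is None:
            raise TrialConsistencyError(
                f"turn trial {self.trial_id!r} lacks reference_onset_ms"
            )
        if not is_turn and self.reference_onset_ms is not None:
            raise TrialConsistencyError(
                f"straight trial {self.trial_id!r} declares reference_onset_ms"
            )
        first = next(iter(self.signals.values()))
        for loc, sig in self.signals.items():
            if sig.n_samples != first.n_samples or sig.sample_rate != first.sample_rate:
                raise TrialConsistencyError(
                    f"location {loc} disagrees in length or sample rate"
                )
        if self.reference_onset_ms is not None:
            if not (self.walk_start_ms <= self.reference_onset_ms < first.duration_ms + 1e-9):
                raise TrialConsistencyError(
                    "require walk_start_ms <= reference_onset_ms < trial duration"
                )

    @property
    def is_turn(self) -> bool:
        return self.path_label != "straight"

    @property
    def amplitude_deg(self) -> int | None:
        return path_amplitude(self.path_label)

    @property
    def direction(self) -> str | None:
        return path_direction(self.path_label)

    @property
    def sample_rate(self) -> float:
        return next(iter(self.signals.values())).sample_rate

    @property
    def n_samples(self) -> int:
        return next(iter(self.signals.values())).n_samples


def baseline_subtract(
    signals: VerticalAxisSignals, baseline_window_s: float = 1.0
) -> VerticalAxisSignals:
    """Zero-reference orientation and heading to the start-of-trial baseline.

    The subject stands still for several seconds before walking; the mean of
    ``angle`` and of ``mag_heading`` over the first ``baseline_window_s``
    seconds is subtracted from the respective full series.  Angular velocity
    is returned unchanged.  Idempotent up to floating point.
    """
    if baseline_window_s <= 0:
        raise ValueError("baseline_window_s must be positive")
    n_window = int(round(baseline_window_s * signals.sample_rate))
    n_window = max(n_window, 1)
    if n_window > signals.n_samples:
        raise ValueError(
            f"baseline window of {baseline_window_s} s ({n_window} samples) exceeds "
            f"series length {signals.n_samples}"
        )
    return replace(
        signals,
        angle=signals.angle - signals.angle[:n_window].mean(),
        mag_heading=signals.mag_heading - signals.mag_heading[:n_window].mean(),
    )


# ---------------------------------------------------------------------------
# Persistence: trial CSV + sidecar JSON, cohort manifest JSON
# ---------------------------------------------------------------------------

def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write one trial as CSV plus a JSON sidecar next to it."""
    csv_path = Path(path)
    columns: dict[str, np.ndarray] = {
        "t_ms": next(iter(trial.signals.values())).times_ms()
    }
    for loc, sig in trial.signals.items():
        columns[f"{loc.value}_gyro_dps"] = sig.angular_velocity
        columns[f"{loc.value}_angle_deg"] = sig.angle
        columns[f"{loc.value}_mag"] = sig.mag_heading
    pd.DataFrame(columns).to_csv(
        csv_path, index=False, float_format=f"%.{CSV_DECIMALS}f"
    )
    sidecar = {
        "subject_id": trial.subject_id,
        "trial_id": trial.trial_id,
        "path_label": trial.path_label,
        "reference_onset_ms": trial.reference_onset_ms,
        "walk_start_ms": trial.walk_start_ms,
        "sample_rate_hz": trial.sample_rate,
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))


def read_trial(path: str | Path) -> TrialRecording:
    """Read a trial written by :func:`write_trial`.

    Raises :class:`TrialFormatError` naming the first missing column, and
    :class:`TrialConsistencyError` on invariant violations (handled by the
    :class:`TrialRecording` constructor).
    """
    csv_path = Path(path)
    sidecar_path = _sidecar_path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(f"trial CSV not found: {csv_path}")
    if not sidecar_path.exists():
        raise TrialFormatError(f"missing sidecar JSON: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("subject_id", "trial_id", "path_label", "walk_start_ms", "sample_rate_hz"):
        if key not in meta:
            raise TrialFormatError(f"sidecar {sidecar_path} lacks field {key!r}")
    frame = pd.read_csv(csv_path)
    if "t_ms" not in frame.columns:
        raise TrialFormatError(f"{csv_path} lacks required column 't_ms'")
    signals: dict[SensorLocation, VerticalAxisSignals] = {}
    for loc in SensorLocation:
        triple = [f"{loc.value}_gyro_dps", f"{loc.value}_angle_deg", f"{loc.value}_mag"]
        present = [c in frame.columns for c in triple]
        if not any(present):
            continue
        if not all(present):
            missing = triple[present.index(False)]
            raise TrialFormatError(f"{csv_path} lacks required column {missing!r}")
        signals[loc] = VerticalAxisSignals(
            angular_velocity=frame[triple[0]].to_numpy(float),
            angle=frame[triple[1]].to_numpy(float),
            mag_heading=frame[triple[2]].to_numpy(float),
            sample_rate=float(meta["sample_rate_hz"]),
        )
    if not signals:
        raise TrialFormatError(f"{csv_path} declares no sensor-location columns")
    onset = meta.get("reference_onset_ms")
    return TrialRecording(
        subject_id=str(meta["subject_id"]),
        trial_id=str(meta["trial_id"]),
        path_label=str(meta["path_label"]),
        signals=signals,
        reference_onset_ms=None if onset is None else float(onset),
        walk_start_ms=float(meta["walk_start_ms"]),
    )


def write_cohort_manifest(
    trials_by_subject: Mapping[str, Sequence[str | Path]], path: str | Path
) -> None:
    """Write a cohort manifest: trial CSV paths grouped by subject."""
    payload = {
        "subjects": {
            subject: [str(p) for p in paths]
            for subject, paths in trials_by_subject.items()
        }
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_cohort(manifest_path: str | Path) -> dict[str, list[TrialRecording]]:
    """Load every trial listed in a manifest, grouped by subject.

    Relative trial paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    payload = json.loads(manifest_path.read_text())
    if "subjects" not in payload:
        raise TrialFormatError(f"manifest {manifest_path} lacks 'subjects' key")
    cohort: dict[str, list[TrialRecording]] = {}
    for subject, paths in payload["subjects"].items():
        trials = []
        for p in paths:
            p = Path(p)
            if not p.is_absolute():
                p = manifest_path.parent / p
            trials.append(read_trial(p))
        cohort[subject] = trials
    return cohort
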