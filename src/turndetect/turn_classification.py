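"""Turn direction and amplitude classification from a three-value snapshot.

At a time ``T = onset + offset`` (offsets of 0–500 ms are evaluated), the
three vertical-axis channels — angular velocity, magnetometer heading and
orientation — are read off as a feature triple.  Direction (left/right)
uses the signed values, whose sign carries the turn direction; amplitude
(22/45/90 deg) uses absolute values, since amplitude is direction-blind.

Classification is linear discriminant analysis: an equal-covariance
Gaussian class model whose decision boundaries are linear.  The model is
stored explicitly (class means, pooled within-class covariance, empirical
priors) so it can be serialized, inspected and transferred between
subjects.  Training features are extracted at the *reference* onset plus
offset (the clean supervised signal); prediction uses the *detected*
onset plus offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from turndetect.imu_signals import SensorLocation, TrialRecording, VerticalAxisSignals

__all__ = [
    "FeatureTriple",
    "DiscriminantModel",
    "extract_features",
    "train_discriminant",
    "classify_direction",
    "classify_amplitude",
    "training_features",
    "DEFAULT_OFFSETS_MS",
]

#: Post-onset feature times evaluated, ms.
DEFAULT_OFFSETS_MS = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0)

#: Ridge added to a singular pooled covariance, as a fraction of trace/3.
_RIDGE = 1e-6


@dataclass(frozen=True)
class FeatureTriple:
    """(angular velocity, magnetometer, orientation) read at one instant."""

    angular_velocity_at_T: float
    mag_at_T: float
    angle_at_T: float
    absolute: bool = False

    def __post_init__(self) -> None:
        if self.absolute and (
            self.angular_velocity_at_T < 0 or self.mag_at_T < 0 or self.angle_at_T < 0
        ):
            raise ValueError("absolute features must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.angular_velocity_at_T, self.mag_at_T, self.angle_at_T], dtype=float
        )


def extract_features(
    signals: VerticalAxisSignals, T_ms: float, absolute: bool
) -> FeatureTriple:
    """Read the three channels at the sample nearest ``T_ms``."""
    idx = signals.index_at(T_ms)
    omega = float(signals.angular_velocity[idx])
    mag = float(signals.mag_heading[idx])
    theta = float(signals.angle[idx])
    if absolute:
        omega, mag, theta = abs(omega), abs(mag), abs(theta)
    return FeatureTriple(omega, mag, theta, absolute=absolute)


@dataclass(frozen=True)
class DiscriminantModel:
    """Linear discriminant classifier with an explicit Gaussian class model.

    ``class_means`` is (C, 3); ``pooled_covariance`` the prior-weighted
    within-class ML covariance (3, 3); ``priors`` the empirical class
    frequencies.  Prediction maximizes the linear discriminant score;
    exact ties break to the first label in ``class_labels`` order.
    """

    class_labels: tuple
    class_means: np.ndarray
    pooled_covariance: np.ndarray
    priors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_means", np.asarray(self.class_means, float))
        object.__setattr__(
            self, "pooled_covariance", np.asarray(self.pooled_covariance, float)
        )
        object.__setattr__(self, "priors", np.asarray(self.priors, float))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        if not np.allclose(self.pooled_covariance, self.pooled_covariance.T, atol=1e-9):
            raise ValueError("pooled covariance must be symmetric")

    def _score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores, shape (n, C)."""
        cov = self.pooled_covariance
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            ridge = _RIDGE * np.trace(cov) / cov.shape[0]
            inv = np.linalg.inv(cov + ridge * np.eye(cov.shape[0]))
        # delta_c(x) = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c
        lin = self.class_means @ inv  # (C, 3)
        const = -0.5 * np.einsum("cj,cj->c", lin, self.class_means) + np.log(
            self.priors
        )
        return X @ lin.T + const

    def predict(self, X: np.ndarray | Sequence[FeatureTriple]):
        """Predicted label(s) for feature rows or FeatureTriples."""
        single = False
        if isinstance(X, FeatureTriple):
            X, single = X.as_array()[None, :], True
        elif len(X) and isinstance(X[0], FeatureTriple):
            X = np.stack([f.as_array() for f in X])
        else:
            X = np.atleast_2d(np.asarray(X, float))
        scores = self._score_matrix(X)
        idx = np.argmax(scores, axis=1)  # argmax takes the first max: tie rule
        labels = [self.class_labels[i] for i in idx]
        return labels[0] if single else labels

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.class_labels),
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DiscriminantModel":
        return cls(
            class_labels=tuple(payload["class_labels"]),
            class_means=np.array(payload["class_means"]),
            pooled_covariance=np.array(payload["pooled_covariance"]),
            priors=np.array(payload["priors"]),
        )

    def save(self, path: str | Path, **extra) -> None:
        Path(path).write_text(json.dumps({**self.to_dict(), **extra}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DiscriminantModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_discriminant(
    features: Sequence[FeatureTriple] | np.ndarray, labels: Sequence
) -> DiscriminantModel:
    """Fit the discriminant from labelled feature triples.

    Class means are per-class sample means; the pooled covariance is the
    prior-weighted within-class ML covariance; priors are empirical class
    frequencies.  Requires at least two classes and two samples per class.
    Invariant to sample order.  A singular pooled covariance is ridged by
    ``1e-6 * trace/3`` on the diagonal.
    """
    if len(features) and isinstance(features[0], FeatureTriple):
        X = np.stack([f.as_array() for f in features])
    else:
        X = np.atleast_2d(np.asarray(features, float))
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("features and labels must have equal length")
    class_labels = tuple(sorted(set(y.tolist())))
    if len(class_labels) < 2:
        raise ValueError("need at least two classes to train")
    n, d = X.shape
    means = np.empty((len(class_labels), d))
    priors = np.empty(len(class_labels))
    pooled = np.zeros((d, d))
    for i, label in enumerate(class_labels):
        Xc = X[y == label]
        if len(Xc) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")
        means[i] = Xc.mean(axis=0)
        priors[i] = len(Xc) / n
        centered = Xc - means[i]
        pooled += priors[i] * (centered.T @ centered) / len(Xc)
    if np.linalg.matrix_rank(pooled) < d:
        pooled = pooled + _RIDGE * np.trace(pooled) / d * np.eye(d)
    return DiscriminantModel(
        class_labels=class_labels,
        class_means=means,
        pooled_covariance=pooled,
        priors=priors,
    )


def training_features(
    trials: Sequence[TrialRecording],
    location: SensorLocation,
    offset_ms: float,
    task: str,
) -> tuple[list[FeatureTriple], list]:
    """Feature/label pairs from turn trials at reference onset + offset.

    ``task`` is ``"direction"`` (signed features, left/right labels) or
    ``"amplitude"`` (absolute features, 22/45/90 labels).  Straight trials
    are skipped.
    """
    if task not in ("direction", "amplitude"):
        raise ValueError("task must be 'direction' or 'amplitude'")
    absolute = task == "amplitude"
    feats: list[FeatureTriple] = []
    labels: list = []
    for trial in trials:
        if not trial.is_turn:
            continue
        sig = trial.signals[location]
        feats.append(
            extract_features(sig, trial.reference_onset_ms + offset_ms, absolute)
        )
        labels.append(trial.direction if task == "direction" else trial.amplitude_deg)
    return feats, labels


def classify_direction(
    model: DiscriminantModel,
    trial: TrialRecording,
    location: SensorLocation,
    onset_ms: float,
    offset_ms: float = 0.0,
) -> str:
    """Predict ``left``/``right`` from signed features at onset + offset."""
    feat = extract_features(trial.signals[location], onset_ms + offset_ms, False)
    return model.predict(feat)


def classify_amplitude(
    model: DiscriminantModel,
    trial: TrialRecording,
    location: SensorLocation,
    onset_ms: float,
    offset_ms: float = 0.0,
) -> int:
    """Predict the turn amplitude (22/45/90) from absolute features."""
    feat = extract_features(trial.signals[location], onset_ms + offset_ms, True)
    return model.predict(feat)
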