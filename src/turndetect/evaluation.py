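"""Evaluation protocol: onset metrics, crossvalidation, amplitude subsets.

Per-trial outcomes are categorized as correct detection (CD, within
tolerance of the reference onset), premature/late detection (PLD), false
negative (FN, turn missed), false positive (FP, detection on a straight
trial) or true negative (TN).  CD, PLD and FN percentages share the
turn-trial denominator and always sum to 100; FP uses the straight-trial
denominator.  DIFF is the mean signed detected-minus-reference onset over
detected turn trials (positive = late).

Two leave-one-out schemes mirror the study: *within-subject* (per subject,
leave one trial out, pool that subject's outcomes, then average the
per-subject percentages) and *subject-independent* (leave one subject
out).  Subjects contribute equally to the averages.  Direction/amplitude
classification accuracy is computed only over correctly detected trials,
per post-onset offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

from turndetect.imu_signals import SensorLocation, TrialRecording
from turndetect.onset_detection import DetectionResult, ThresholdPair, detect_onset
from turndetect.threshold_training import TrainingConfig, optimize_thresholds
from turndetect.turn_classification import (
    DEFAULT_OFFSETS_MS,
    classify_amplitude,
    classify_direction,
    train_discriminant,
    training_features,
)

__all__ = [
    "TrialOutcome",
    "EvaluationReport",
    "score_trial",
    "aggregate",
    "Fold",
    "iter_folds",
    "crossvalidate",
    "subset_by_amplitude",
]

CATEGORIES = ("CD", "PLD", "FN", "FP", "TN")
SCHEMES = ("within_subject", "subject_independent")


@dataclass(frozen=True)
class TrialOutcome:
    """Detection outcome of one trial; ``diff_ms`` only for CD/PLD."""

    category: str
    diff_ms: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in ("CD", "PLD"):
            if self.diff_ms is None:
                raise ValueError(f"{self.category} outcomes need diff_ms")
        elif self.diff_ms is not None:
            raise ValueError(f"{self.category} outcomes carry no diff_ms")


@dataclass(frozen=True)
class EvaluationReport:
    """Onset metrics (and optional per-offset accuracies) for one trial set.

    All percentages are in [0, 100]; ``cd_pct + pld_pct + fn_pct == 100``.
    ``fp_pct`` is None when the set held no straight trials, ``diff_ms_mean``
    None when nothing was detected.  Accuracy dicts map post-onset offset
    (ms) to percent correct over correctly detected turn trials.
    """

    cd_pct: float
    pld_pct: float
    fn_pct: float
    fp_pct: float | None
    diff_ms_mean: float | None
    n_turn_trials: int
    n_straight_trials: int
    direction_accuracy_pct: dict[float, float] | None = None
    amplitude_accuracy_pct: dict[float, float] | None = None
    per_subject: dict[str, "EvaluationReport"] | None = None

    def __post_init__(self) -> None:
        if abs(self.cd_pct + self.pld_pct + self.fn_pct - 100.0) > 1e-9:
            raise ValueError("CD + PLD + FN must equal 100")
        for name in ("cd_pct", "pld_pct", "fn_pct", "fp_pct"):
            v = getattr(self, name)
            if v is not None and not (-1e-9 <= v <= 100.0 + 1e-9):
                raise ValueError(f"{name}={v} outside [0, 100]")

    def to_dict(self) -> dict:
        out = {
            "cd_pct": self.cd_pct,
            "pld_pct": self.pld_pct,
            "fn_pct": self.fn_pct,
            "fp_pct": self.fp_pct,
            "diff_ms_mean": self.diff_ms_mean,
            "n_turn_trials": self.n_turn_trials,
            "n_straight_trials": self.n_straight_trials,
        }
        if self.direction_accuracy_pct is not None:
            out["direction_accuracy_pct"] = dict(self.direction_accuracy_pct)
        if self.amplitude_accuracy_pct is not None:
            out["amplitude_accuracy_pct"] = dict(self.amplitude_accuracy_pct)
        if self.per_subject is not None:
            out["per_subject"] = {
                s: r.to_dict() for s, r in self.per_subject.items()
            }
        return out


def score_trial(
    trial: TrialRecording, result: DetectionResult, tolerance_ms: float = 500.0
) -> TrialOutcome:
    """Categorize one trial's detection result against its ground truth."""
    if trial.is_turn:
        if not result.detected:
            return TrialOutcome("FN")
        diff = result.onset_ms - trial.reference_onset_ms
        category = "CD" if abs(diff) <= tolerance_ms else "PLD"
        return TrialOutcome(category, diff_ms=diff)
    return TrialOutcome("FP") if result.detected else TrialOutcome("TN")


def aggregate(outcomes: Sequence[TrialOutcome]) -> EvaluationReport:
    """Fold a list of outcomes into the standard metric percentages."""
    if not outcomes:
        raise ValueError("cannot aggregate an empty outcome list")
    counts = {c: sum(1 for o in outcomes if o.category == c) for c in CATEGORIES}
    n_turn = counts["CD"] + counts["PLD"] + counts["FN"]
    n_straight = counts["FP"] + counts["TN"]
    if n_turn == 0:
        raise ValueError("need at least one turn trial for CD/PLD/FN")
    diffs = [o.diff_ms for o in outcomes if o.diff_ms is not None]
    return EvaluationReport(
        cd_pct=100.0 * counts["CD"] / n_turn,
        pld_pct=100.0 * counts["PLD"] / n_turn,
        fn_pct=100.0 * counts["FN"] / n_turn,
        fp_pct=(100.0 * counts["FP"] / n_straight) if n_straight else None,
        diff_ms_mean=float(np.mean(diffs)) if diffs else None,
        n_turn_trials=n_turn,
        n_straight_trials=n_straight,
    )


@dataclass(frozen=True)
class Fold:
    """One crossvalidation fold; test trials all belong to ``subject_id``."""

    subject_id: str
    train: tuple[TrialRecording, ...]
    test: tuple[TrialRecording, ...]


def iter_folds(
    cohort: Mapping[str, Sequence[TrialRecording]], scheme: str
) -> Iterator[Fold]:
    """Leave-one-out folds for either scheme.

    ``subject_independent``: one fold per held-out subject, trained on all
    other subjects.  ``within_subject``: one fold per held-out trial,
    trained on the same subject's remaining trials.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    subjects = list(cohort)
    if scheme == "subject_independent":
        if len(subjects) < 2:
            raise ValueError("subject_independent needs >= 2 subjects")
        for held_out in subjects:
            train = tuple(
                t for s in subjects if s != held_out for t in cohort[s]
            )
            yield Fold(held_out, train, tuple(cohort[held_out]))
    else:
        for subject in subjects:
            trials = list(cohort[subject])
            if len(trials) < 2:
                raise ValueError("within_subject needs >= 2 trials per subject")
            for i, held_out in enumerate(trials):
                train = tuple(trials[:i] + trials[i + 1:])
                yield Fold(subject, train, (held_out,))


def _classification_models(
    train: Sequence[TrialRecording],
    location: SensorLocation,
    offsets_ms: Sequence[float],
):
    models = {}
    for offset in offsets_ms:
        for task in ("direction", "amplitude"):
            feats, labels = training_features(train, location, offset, task)
            models[(offset, task)] = train_discriminant(feats, labels)
    return models


def _average(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def crossvalidate(
    cohort: Mapping[str, Sequence[TrialRecording]],
    scheme: str,
    location: SensorLocation,
    config: TrainingConfig,
    offsets_ms: Sequence[float] = DEFAULT_OFFSETS_MS,
    classify: bool = True,
    detect_fn: Callable[[TrialRecording, SensorLocation], DetectionResult] | None = None,
) -> EvaluationReport:
    """Leave-one-out crossvalidation of detection (and classification).

    Per fold, detection thresholds are optimized on the training trials and
    applied to the held-out trials; per-offset discriminant models are
    trained on the same fold and scored only on correctly detected turn
    trials.  Outcomes are pooled per subject, turned into percentages, then
    averaged unweighted across subjects.  ``detect_fn`` substitutes an
    externally supplied detector (no threshold training), e.g. an oracle.
    """
    per_subject_outcomes: dict[str, list[TrialOutcome]] = {}
    per_subject_cls: dict[str, dict[tuple[float, str], list[bool]]] = {}

    for fold in iter_folds(cohort, scheme):
        if detect_fn is None:
            thresholds, _ = optimize_thresholds(list(fold.train), location, config)
            run = lambda trial: detect_onset(  # noqa: E731
                trial.signals[location], thresholds, config.search_start_ms
            )
        else:
            run = lambda trial: detect_fn(trial, location)  # noqa: E731
        models = (
            _classification_models(fold.train, location, offsets_ms)
            if classify
            else None
        )
        outcomes = per_subject_outcomes.setdefault(fold.subject_id, [])
        cls = per_subject_cls.setdefault(fold.subject_id, {})
        for trial in fold.test:
            result = run(trial)
            outcome = score_trial(trial, result, config.tolerance_ms)
            outcomes.append(outcome)
            if models is None or outcome.category != "CD":
                continue
            for offset in offsets_ms:
                d = classify_direction(
                    models[(offset, "direction")], trial, location,
                    result.onset_ms, offset,
                )
                a = classify_amplitude(
                    models[(offset, "amplitude")], trial, location,
                    result.onset_ms, offset,
                )
                cls.setdefault((offset, "direction"), []).append(d == trial.direction)
                cls.setdefault((offset, "amplitude"), []).append(
                    a == trial.amplitude_deg
                )

    per_subject: dict[str, EvaluationReport] = {}
    for subject, outcomes in per_subject_outcomes.items():
        base = aggregate(outcomes)
        if classify:
            cls = per_subject_cls[subject]
            direction = {
                o: 100.0 * float(np.mean(cls[(o, "direction")]))
                for o in offsets_ms
                if (o, "direction") in cls
            }
            amplitude = {
                o: 100.0 * float(np.mean(cls[(o, "amplitude")]))
                for o in offsets_ms
                if (o, "amplitude") in cls
            }
            base = EvaluationReport(
                **{**base.__dict__,
                   "direction_accuracy_pct": direction or None,
                   "amplitude_accuracy_pct": amplitude or None},
            )
        per_subject[subject] = base

    reports = list(per_subject.values())
    direction_avg = amplitude_avg = None
    if classify:
        direction_avg = {
            o: v
            for o in offsets_ms
            if (v := _average([
                r.direction_accuracy_pct[o]
                for r in reports
                if r.direction_accuracy_pct and o in r.direction_accuracy_pct
            ])) is not None
        }
        amplitude_avg = {
            o: v
            for o in offsets_ms
            if (v := _average([
                r.amplitude_accuracy_pct[o]
                for r in reports
                if r.amplitude_accuracy_pct and o in r.amplitude_accuracy_pct
            ])) is not None
        }
    return EvaluationReport(
        cd_pct=float(np.mean([r.cd_pct for r in reports])),
        pld_pct=float(np.mean([r.pld_pct for r in reports])),
        fn_pct=float(np.mean([r.fn_pct for r in reports])),
        fp_pct=_average([r.fp_pct for r in reports if r.fp_pct is not None]),
        diff_ms_mean=_average(
            [r.diff_ms_mean for r in reports if r.diff_ms_mean is not None]
        ),
        n_turn_trials=sum(r.n_turn_trials for r in reports),
        n_straight_trials=sum(r.n_straight_trials for r in reports),
        direction_accuracy_pct=direction_avg or None,
        amplitude_accuracy_pct=amplitude_avg or None,
        per_subject=per_subject,
    )


def subset_by_amplitude(
    cohort: Sequence[TrialRecording], keep: set[int]
) -> list[TrialRecording]:
    """Keep straight trials and turns whose amplitude is in ``keep``.

    Models applications where only larger turns can occur (e.g. 45/90 only);
    applied identically to training and test folds.
    """
    if not keep:
        raise ValueError("keep must name at least one amplitude")
    if not keep <= {22, 45, 90}:
        raise ValueError(f"amplitudes must be among 22/45/90, got {sorted(keep)}")
    return [
        t for t in cohort if not t.is_turn or t.amplitude_deg in keep
    ]
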