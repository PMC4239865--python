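"""Shared fixtures: synthetic cohorts and hand-constructed trials."""

from __future__ import annotations

import numpy as np
import pytest

from turndetect.imu_signals import (
    SensorLocation,
    TrialRecording,
    VerticalAxisSignals,
)
from turndetect.synthetic_gait import GeneratorConfig, generate_cohort_trials

UB = SensorLocation.UPPER_BACK


def make_signals(
    omega=None, theta=None, mag=None, n: int = 1000, fs: float = 100.0
) -> VerticalAxisSignals:
    """Build a signal triple from arrays (missing channels default to zero)."""
    for arr in (omega, theta, mag):
        if arr is not None:
            n = len(arr)
            break
    if omega is None:
        omega = np.zeros(n)
    if theta is None:
        theta = np.zeros(n)
    if mag is None:
        mag = np.zeros(n)
    return VerticalAxisSignals(
        angular_velocity=np.asarray(omega, float),
        angle=np.asarray(theta, float),
        mag_heading=np.asarray(mag, float),
        sample_rate=fs,
    )


def make_trial(
    signals: VerticalAxisSignals,
    path_label: str = "left_90",
    reference_onset_ms: float | None = 5000.0,
    walk_start_ms: float = 2000.0,
    subject_id: str = "T01",
    trial_id: str = "t000",
    location: SensorLocation = UB,
) -> TrialRecording:
    """Single-location trial around hand-constructed signals."""
    if path_label == "straight":
        reference_onset_ms = None
    return TrialRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        path_label=path_label,
        signals={location: signals},
        reference_onset_ms=reference_onset_ms,
        walk_start_ms=walk_start_ms,
    )


def spike_trial(
    spike_ms: float | None,
    path_label: str = "left_90",
    reference_onset_ms: float | None = 5000.0,
    n: int = 1200,
    trial_id: str = "t000",
) -> TrialRecording:
    """Trial whose gyro is zero except one 100 deg/s spike (or none)."""
    omega = np.zeros(n)
    if spike_ms is not None:
        omega[int(round(spike_ms / 10.0))] = 100.0
    return make_trial(
        make_signals(omega=omega, n=n),
        path_label=path_label,
        reference_onset_ms=reference_onset_ms,
        trial_id=trial_id,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-scale cohort: 10 subjects x 49 trials, seed 1."""
    return generate_cohort_trials(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 14 trials (2 blocks) — fast crossvalidation runs."""
    return generate_cohort_trials(GeneratorConfig(seed=5, n_subjects=3, blocks=2))
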