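"""Synthetic gait-trial generator emulating the turning-study protocol.

Each subject performs 49 trials in 7 blocks; every block presents the 7
travel paths (straight, left/right x 22/45/90 deg) in random order.  A
trial begins with a standing phase (~5 s plus reaction time), walking
starts ~8.3 s into the trial and, on turn trials, the turn begins ~10.2 s
in; a full trial lasts ~16.4 s.

Turn kinematics use a logistic orientation profile per body segment:

    theta_loc(t) = A * L((t - t0 - lag_loc) / tau) + osc(t) + drift(t)

with ``L`` the standard logistic, ``A`` the signed amplitude (positive =
left), ``tau`` an amplitude- and profile-dependent time scale, and
``lag_loc`` encoding the top-down turning strategy of healthy adults: the
head reorients first, then trunk, pelvis and finally the feet.  The
closed-form peak angular velocity is ``A / (4 tau)``.  Ground-truth turn
onset is the instant the lag-free logistic reaches 5% of ``A``.

Superimposed nuisance structure: per-step yaw oscillation of the gait
cycle (larger on the legs), a slow heading random walk, standing sway,
white gyroscope noise, magnetometer disturbance near the ground (feet),
and anticipatory head glances toward the trial endpoint that make the
head channel realistically unreliable for turn detection.

The ``amputee`` profile lowers the peak turn speeds (longer ``tau``),
mimicking the slower turning of a transfemoral amputee: 22 and 45 degree
turns then peak below the gyro-threshold range trained on healthy gait.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from turndetect.imu_signals import (
    PATH_LABELS,
    SensorLocation,
    TrialRecording,
    VerticalAxisSignals,
    signed_amplitude,
    write_cohort_manifest,
    write_trial,
)
from turndetect.onset_detection import ThresholdPair

__all__ = [
    "GeneratorConfig",
    "generate_trial",
    "generate_session",
    "generate_cohort_trials",
    "generate_cohort",
    "turn_tau",
    "peak_angular_velocity",
    "threshold_crossing_delay_s",
]

#: logit(0.95) - the x at which the logistic has risen to 95%; the 5%
#: ground-truth onset level sits at -LOGIT95.
_LOGIT95 = float(logit(0.95))

#: Healthy peak turn speeds (deg/s) per amplitude; tau = A / (4 * peak).
#: 45/90 deg turns peak above, 22 deg below, typical trained gyro thresholds.
HEALTHY_PEAK_DPS = {22: 40.0, 45: 80.0, 90: 75.0}

#: Amputee profile: slower turning, smaller angular-velocity peaks; 22 and
#: 45 deg turns fall below the healthy-trained gyro-threshold range.
AMPUTEE_PEAK_DPS = {22: 20.0, 45: 33.0, 90: 48.0}

_DEFAULT_LAGS_MS = {
    SensorLocation.HEAD: -200.0,
    SensorLocation.UPPER_BACK: 0.0,
    SensorLocation.LOWER_BACK: 30.0,
    SensorLocation.LEFT_THIGH: 100.0,
    SensorLocation.RIGHT_THIGH: 100.0,
    SensorLocation.LEFT_SHANK: 150.0,
    SensorLocation.RIGHT_SHANK: 150.0,
    SensorLocation.LEFT_FOOT: 200.0,
    SensorLocation.RIGHT_FOOT: 200.0,
}

_DEFAULT_OSC_AMP_DEG = {
    SensorLocation.HEAD: 1.2,
    SensorLocation.UPPER_BACK: 1.0,
    SensorLocation.LOWER_BACK: 1.5,
    SensorLocation.LEFT_THIGH: 2.0,
    SensorLocation.RIGHT_THIGH: 2.0,
    SensorLocation.LEFT_SHANK: 2.2,
    SensorLocation.RIGHT_SHANK: 2.2,
    SensorLocation.LEFT_FOOT: 2.5,
    SensorLocation.RIGHT_FOOT: 2.5,
}

#: The six locations evaluated in the study (right-side IMUs behave like
#: their left counterparts and are available via ``locations``).
DEFAULT_LOCATIONS = (
    SensorLocation.HEAD,
    SensorLocation.UPPER_BACK,
    SensorLocation.LOWER_BACK,
    SensorLocation.LEFT_THIGH,
    SensorLocation.LEFT_SHANK,
    SensorLocation.LEFT_FOOT,
)

#: SD of the post-onset trial remainder draw, s (see timing construction).
_POST_SD_S = 1.5
#: Walk-to-turn gap draw: mean = onset mean - walk mean, this SD, floor 0.4 s.
_GAP_SD_S = 0.7


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Timing means/SDs are the study's reported statistics; turn kinematics,
    nuisance amplitudes and segment lags are the generator's own realistic
    defaults (documented in the methods note), all configurable.
    """

    seed: int = 1
    n_subjects: int = 10
    blocks: int = 7
    sample_rate: float = 100.0
    trial_duration_s: tuple[float, float] = (16.4, 2.2)  # mean, sd
    walk_start_s: tuple[float, float] = (8.3, 2.3)
    turn_onset_s: tuple[float, float] = (10.2, 2.3)
    profile: str = "healthy"  # "healthy" | "amputee"
    peak_turn_speed_dps: Mapping[int, float] | None = None  # default per profile
    subject_speed_range: tuple[float, float] = (0.9, 1.35)  # multiplies tau
    segment_lag_ms: Mapping[SensorLocation, float] = field(
        default_factory=lambda: dict(_DEFAULT_LAGS_MS)
    )
    gait_osc_amp_deg: Mapping[SensorLocation, float] = field(
        default_factory=lambda: dict(_DEFAULT_OSC_AMP_DEG)
    )
    step_freq_hz: float = 1.9
    step_freq_subject_sd: float = 0.15
    step_amp_jitter: float = 0.5
    heading_drift_sd: float = 0.4  # deg / sqrt(s), walking phase random walk
    noise_sd_dps: float = 4.0  # white noise on angular velocity
    sway_deg: float = 0.3
    sway_freq_hz: float = 0.25
    head_anticipation_prob: float = 0.6
    head_anticipation_deg: tuple[float, float] = (10.0, 30.0)
    head_glance_tau_s: float = 0.15
    mag_gain: float = 1.0
    mag_noise_sd: float = 0.5
    foot_mag_disturb_sd: float = 5.0
    onset_level: float = 0.05
    locations: tuple[SensorLocation, ...] = DEFAULT_LOCATIONS

    def __post_init__(self) -> None:
        if self.profile not in ("healthy", "amputee"):
            raise ValueError("profile must be 'healthy' or 'amputee'")
        for name in (
            "heading_drift_sd",
            "noise_sd_dps",
            "sway_deg",
            "mag_noise_sd",
            "foot_mag_disturb_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.onset_level < 0.5):
            raise ValueError("onset_level must lie in (0, 0.5)")
        if self.sample_rate <= 0 or self.blocks < 1 or self.n_subjects < 1:
            raise ValueError("sample_rate, blocks, n_subjects must be positive")

    @property
    def peaks(self) -> Mapping[int, float]:
        if self.peak_turn_speed_dps is not None:
            return self.peak_turn_speed_dps
        return HEALTHY_PEAK_DPS if self.profile == "healthy" else AMPUTEE_PEAK_DPS

    def noise_free(self) -> "GeneratorConfig":
        """Deterministic-kinematics variant: pure logistic turns, no nuisance."""
        return replace(
            self,
            gait_osc_amp_deg={loc: 0.0 for loc in SensorLocation},
            step_amp_jitter=0.0,
            heading_drift_sd=0.0,
            noise_sd_dps=0.0,
            sway_deg=0.0,
            head_anticipation_prob=0.0,
            mag_noise_sd=0.0,
            foot_mag_disturb_sd=0.0,
            subject_speed_range=(1.0, 1.0),
        )


def turn_tau(config: GeneratorConfig, amplitude: int, tau_factor: float = 1.0) -> float:
    """Logistic time scale for one amplitude, s: tau = A / (4 * peak)."""
    return amplitude / (4.0 * config.peaks[amplitude]) * tau_factor


def peak_angular_velocity(config: GeneratorConfig, amplitude: int,
                          tau_factor: float = 1.0) -> float:
    """Closed-form peak |omega| of the logistic turn, deg/s."""
    return amplitude / (4.0 * turn_tau(config, amplitude, tau_factor))


def threshold_crossing_delay_s(
    amplitude: float,
    tau: float,
    thresholds: ThresholdPair,
    onset_level: float = 0.05,
) -> float:
    """Closed-form delay from ground-truth onset to threshold crossing.

    For the lag-free, noise-free logistic turn: the angle criterion fires
    when ``A * L(x) = angle_thresh`` and the gyro criterion when
    ``(A / tau) * L(x)(1 - L(x)) = gyr_thresh`` (first crossing, rising
    branch).  Returns the earliest enabled crossing, in seconds after the
    ``onset_level`` ground-truth onset; ``inf`` if neither fires.
    """
    A = abs(amplitude)
    x_onset = float(logit(onset_level))
    candidates = []
    if thresholds.uses_angle and thresholds.angle_thresh < A:
        candidates.append(float(logit(thresholds.angle_thresh / A)))
    if thresholds.uses_gyro:
        q = thresholds.gyr_thresh * tau / A
        if q < 0.25:
            lower = (1.0 - np.sqrt(1.0 - 4.0 * q)) / 2.0
            candidates.append(float(logit(lower)))
    if not candidates:
        return float("inf")
    return (min(candidates) - x_onset) * tau


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _SubjectParams:
    tau_factor: float
    step_freq_hz: float


def _draw_subject(config: GeneratorConfig, rng: np.random.Generator) -> _SubjectParams:
    lo, hi = config.subject_speed_range
    return _SubjectParams(
        tau_factor=float(rng.uniform(lo, hi)),
        step_freq_hz=float(max(rng.normal(config.step_freq_hz,
                                          config.step_freq_subject_sd), 1.2)),
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      minimum: float) -> float:
    if sd == 0:
        return max(mean, minimum)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= minimum:
            return float(x)
    return float(minimum)  # pragma: no cover - pathological configuration


def _draw_timing(
    config: GeneratorConfig, rng: np.random.Generator, tau: float, is_turn: bool
) -> tuple[float, float, float]:
    """(walk_start_s, onset_s, duration_s) honoring ordering constraints.

    Onset is drawn marginally at the configured mean/SD; walk start is
    onset minus a truncated gap whose mean equals the configured spacing,
    and duration is onset plus a truncated remainder long enough for the
    turn to complete with >= 1 s of post-offset signal.  This preserves
    the configured *means* under the ordering constraints (the marginal
    SDs of walk start and duration deviate slightly; see methods note).
    """
    onset_mean, onset_sd = config.turn_onset_s
    walk_mean, _ = config.walk_start_s
    dur_mean, _ = config.trial_duration_s
    onset = _truncated_normal(rng, onset_mean, onset_sd, 4.0)
    gap = _truncated_normal(rng, onset_mean - walk_mean, _GAP_SD_S, 0.4)
    walk_start = onset - gap
    tail = (2.0 * _LOGIT95 * tau + 1.2) if is_turn else 2.0
    post = _truncated_normal(rng, dur_mean - onset_mean, _POST_SD_S, tail)
    return walk_start, onset, onset + post


def generate_trial(
    config: GeneratorConfig,
    path_label: str,
    rng: np.random.Generator,
    subject: _SubjectParams | None = None,
    subject_id: str = "S00",
    trial_id: str = "t000",
) -> TrialRecording:
    """Synthesize one trial for every configured sensor location."""
    if path_label not in PATH_LABELS:
        raise ValueError(f"unknown path_label {path_label!r}")
    if subject is None:
        subject = _draw_subject(config, rng)
    fs = config.sample_rate
    dt = 1.0 / fs
    A = signed_amplitude(path_label)
    is_turn = A != 0.0
    tau = turn_tau(config, int(abs(A)), subject.tau_factor) if is_turn else 0.2
    walk_start, onset, duration = _draw_timing(config, rng, tau, is_turn)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) * dt
    t0 = onset + _LOGIT95 * tau  # logistic midpoint: onset is the 5% crossing

    walking = t >= walk_start
    ramp = np.clip((t - walk_start) / 0.6, 0.0, 1.0)  # 0.6 s gait spin-up

    # per-step amplitude jitter of the yaw oscillation, interpolated
    # linearly between steps so its derivative stays small
    f_step = subject.step_freq_hz
    n_steps = int(np.ceil(duration * f_step)) + 2
    step_factors = 1.0 + config.step_amp_jitter * rng.uniform(-1.0, 1.0, n_steps)
    step_times = walk_start + np.arange(n_steps) / f_step
    step_factor_t = np.interp(t, step_times, step_factors)
    osc_phase = rng.uniform(0.0, 2.0 * np.pi)

    # heading random walk, shared walking-phase draw reused per location is
    # not physical: each segment drifts on its own
    signals = {}
    glance = None
    if (
        SensorLocation.HEAD in config.locations
        and rng.random() < config.head_anticipation_prob
    ):
        m_lo, m_hi = config.head_anticipation_deg
        magnitude = rng.uniform(m_lo, m_hi)
        sign = np.sign(A) if is_turn else rng.choice([-1.0, 1.0])
        t1 = max(1.5, walk_start - rng.uniform(0.0, 1.0))
        t2 = t1 + rng.uniform(1.0, 2.0)
        glance = (float(sign * magnitude), t1, t2)

    for loc in config.locations:
        lag = config.segment_lag_ms.get(loc, 0.0) / 1000.0
        if is_turn:
            x = (t - t0 - lag) / tau
            sig = expit(x)
            theta_turn = A * sig
            omega_turn = A / tau * sig * (1.0 - sig)
        else:
            theta_turn = np.zeros(n)
            omega_turn = np.zeros(n)

        amp = config.gait_osc_amp_deg.get(loc, 0.0)
        theta_osc = (
            amp
            * step_factor_t
            * ramp
            * np.sin(2.0 * np.pi * f_step * (t - walk_start) + osc_phase)
        )
        if config.heading_drift_sd > 0:
            steps = rng.normal(0.0, config.heading_drift_sd * np.sqrt(dt), n)
            steps[~walking] = 0.0
            drift = np.cumsum(steps)
        else:
            drift = np.zeros(n)
        sway = config.sway_deg * np.sin(
            2.0 * np.pi * config.sway_freq_hz * t + rng.uniform(0.0, 2.0 * np.pi)
        )
        theta_other = theta_osc + drift + sway
        if loc is SensorLocation.HEAD and glance is not None:
            m, t1, t2 = glance
            tau_g = config.head_glance_tau_s
            theta_other = theta_other + m * (
                expit((t - t1) / tau_g) - expit((t - t2) / tau_g)
            )
        theta = theta_turn + theta_other
        omega = omega_turn + np.gradient(theta_other, dt)
        if config.noise_sd_dps > 0:
            omega = omega + rng.normal(0.0, config.noise_sd_dps, n)
        mag = config.mag_gain * theta
        mag_sd = config.mag_noise_sd
        if loc in (SensorLocation.LEFT_FOOT, SensorLocation.RIGHT_FOOT):
            mag_sd = np.hypot(mag_sd, config.foot_mag_disturb_sd)
        if mag_sd > 0:
            mag = mag + rng.normal(0.0, mag_sd, n)
        signals[loc] = VerticalAxisSignals(
            angular_velocity=omega, angle=theta, mag_heading=mag, sample_rate=fs
        )

    return TrialRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        path_label=path_label,
        signals=signals,
        reference_onset_ms=onset * 1000.0 if is_turn else None,
        walk_start_ms=walk_start * 1000.0,
    )


def _subject_rng(config: GeneratorConfig, subject_id: str) -> np.random.Generator:
    # stable across runs and platforms; independent streams per subject
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(subject_id.encode())]
    )


def generate_session(config: GeneratorConfig, subject_id: str) -> list[TrialRecording]:
    """One subject's session: ``blocks`` seeded permutations of the 7 paths."""
    rng = _subject_rng(config, subject_id)
    subject = _draw_subject(config, rng)
    trials: list[TrialRecording] = []
    i = 0
    for _ in range(config.blocks):
        for path in rng.permutation(PATH_LABELS):
            trials.append(
                generate_trial(
                    config,
                    str(path),
                    rng,
                    subject=subject,
                    subject_id=subject_id,
                    trial_id=f"{subject_id}_t{i:03d}",
                )
            )
            i += 1
    return trials


def generate_cohort_trials(config: GeneratorConfig) -> dict[str, list[TrialRecording]]:
    """In-memory cohort: ``n_subjects`` sessions keyed by subject id."""
    return {
        f"S{i + 1:02d}": generate_session(config, f"S{i + 1:02d}")
        for i in range(config.n_subjects)
    }


def generate_cohort(config: GeneratorConfig, out_dir: str | Path) -> Path:
    """Write a cohort to disk (per-subject trial CSV/JSON + manifest).

    Returns the manifest path.  Regeneration at the same seed is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    for subject_id, trials in generate_cohort_trials(config).items():
        subject_dir = out_dir / subject_id
        subject_dir.mkdir(exist_ok=True)
        paths = []
        for trial in trials:
            rel = f"{subject_id}/{trial.trial_id}.csv"
            write_trial(trial, out_dir / rel)
            paths.append(rel)
        manifest[subject_id] = paths
    manifest_path = out_dir / "manifest.json"
    write_cohort_manifest(manifest, manifest_path)
    return manifest_path
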