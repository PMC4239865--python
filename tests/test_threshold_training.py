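"""Error-counting cost function and the threshold optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turndetect.imu_signals import SensorLocation
from turndetect.onset_detection import ThresholdPair, detect_onset
from turndetect.threshold_training import (
    CostSurface,
    TrainingConfig,
    cost,
    grid_min_cost,
    optimize_thresholds,
)

from .conftest import UB, make_signals, make_trial, spike_trial

GYRO_CFG = TrainingConfig(criterion="gyro_only", search_start_ms=1000.0)


class TestCost:
    def test_empty_database_costs_zero(self):
        assert cost(ThresholdPair.gyro_only(58.0), [], UB, GYRO_CFG).num_errors == 0

    def test_detection_at_reference_costs_zero(self):
        trial = spike_trial(5000.0, reference_onset_ms=5000.0)
        assert cost(ThresholdPair.gyro_only(58.0), [trial], UB, GYRO_CFG).num_errors == 0

    def test_detection_600ms_late_costs_one(self):
        trial = spike_trial(5600.0, reference_onset_ms=5000.0)
        assert cost(ThresholdPair.gyro_only(58.0), [trial], UB, GYRO_CFG).num_errors == 1

    def test_detection_within_half_second_is_free(self):
        trial = spike_trial(5499.0 // 10 * 10, reference_onset_ms=5000.0)
        assert cost(ThresholdPair.gyro_only(58.0), [trial], UB, GYRO_CFG).num_errors == 0

    def test_four_branch_database_matches_enumeration(self):
        # CD, late-by-600ms, FN, straight-with-detection
        db = [
            spike_trial(5000.0, reference_onset_ms=5000.0, trial_id="cd"),
            spike_trial(5600.0, reference_onset_ms=5000.0, trial_id="pld"),
            spike_trial(None, reference_onset_ms=5000.0, trial_id="fn"),
            spike_trial(4000.0, path_label="straight", trial_id="fp"),
        ]
        config = GYRO_CFG
        th = ThresholdPair.gyro_only(58.0)
        # independent oracle: enumerate the four pseudocode branches
        expected = 0
        for trial in db:
            result = detect_onset(trial.signals[UB], th, config.search_start_ms)
            if trial.is_turn:
                if result.detected:
                    if abs(result.onset_ms - trial.reference_onset_ms) > 500.0:
                        expected += 1
                else:
                    expected += 1
            elif result.detected:
                expected += 1
        assert expected == 3
        assert cost(th, db, UB, config).num_errors == expected

    def test_error_weights_scale_each_branch(self):
        db = [
            spike_trial(5600.0, reference_onset_ms=5000.0, trial_id="pld"),
            spike_trial(None, reference_onset_ms=5000.0, trial_id="fn"),
            spike_trial(4000.0, path_label="straight", trial_id="fp"),
        ]
        config = TrainingConfig(
            criterion="gyro_only", error_weights=(2.0, 5.0, 11.0)
        )
        assert cost(ThresholdPair.gyro_only(58.0), db, UB, config).num_errors == 18.0

    def test_missing_location_is_a_data_error(self):
        trial = spike_trial(5000.0)
        with pytest.raises(KeyError):
            cost(ThresholdPair.gyro_only(58.0), [trial], SensorLocation.HEAD, GYRO_CFG)

    @settings(derandomize=True, max_examples=20)
    @given(
        seed=st.integers(0, 2**16),
        tol_lo=st.floats(100.0, 400.0),
        extra=st.floats(0.0, 1000.0),
    )
    def test_larger_tolerance_never_costs_more(self, seed, tol_lo, extra):
        rng = np.random.default_rng(seed)
        db = [
            make_trial(
                make_signals(omega=rng.normal(0, 40, 1200), n=1200),
                reference_onset_ms=float(rng.uniform(3000, 8000)),
                trial_id=f"t{i}",
            )
            for i in range(5)
        ]
        th = ThresholdPair.gyro_only(60.0)
        lo = cost(th, db, UB, TrainingConfig(criterion="gyro_only", tolerance_ms=tol_lo))
        hi = cost(
            th, db, UB,
            TrainingConfig(criterion="gyro_only", tolerance_ms=tol_lo + extra),
        )
        assert hi.num_errors <= lo.num_errors


class TestCostSurface:
    @settings(derandomize=True, max_examples=15)
    @given(seed=st.integers(0, 2**16))
    def test_surface_reproduces_direct_cost(self, seed):
        """Vectorized envelope evaluation == per-trial detect_onset path."""
        rng = np.random.default_rng(seed)
        db = []
        for i in range(6):
            is_turn = i % 3 != 2
            db.append(
                make_trial(
                    make_signals(
                        omega=rng.normal(0, 40, 900),
                        theta=np.cumsum(rng.normal(0, 0.3, 900)),
                        n=900,
                    ),
                    path_label="left_45" if is_turn else "straight",
                    reference_onset_ms=float(rng.uniform(2000, 6000)) if is_turn else None,
                    walk_start_ms=1000.0,
                    trial_id=f"t{i}",
                )
            )
        config = TrainingConfig(criterion="combined")
        surface = CostSurface(db, UB, config)
        gyr = rng.uniform(1.0, 150.0, 40)
        ang = rng.uniform(0.5, 60.0, 40)
        fast = surface.evaluate(gyr, ang)
        direct = [
            cost(ThresholdPair.combined(g, a), db, UB, config).num_errors
            for g, a in zip(gyr, ang)
        ]
        assert np.array_equal(fast, np.array(direct))


class TestOptimize:
    def test_all_zero_straight_trial_reaches_zero_cost(self):
        db = [make_trial(make_signals(n=1200), path_label="straight",
                         trial_id="s0")]
        _, best = optimize_thresholds(db, UB, TrainingConfig(criterion="combined"))
        assert best.num_errors == 0

    def test_separable_database_finds_zero_cost_band(self):
        # every turn exceeds 80 deg/s within tolerance; straight trials
        # never exceed 30 deg/s -> zero cost with gyr_thresh in (30, 80]
        rng = np.random.default_rng(3)
        db = []
        for i in range(6):
            omega = rng.uniform(-30, 30, 1200) * 0.9
            ref = None
            label = "straight"
            if i % 2 == 0:
                ref = float(rng.uniform(4000, 8000))
                omega[int(ref / 10)] = 85.0
                label = "left_90"
            db.append(
                make_trial(make_signals(omega=omega, n=1200), path_label=label,
                           reference_onset_ms=ref, trial_id=f"t{i}")
            )
        config = TrainingConfig(criterion="gyro_only", optimizer_seed=7)
        pair, best = optimize_thresholds(db, UB, config)
        assert best.num_errors == 0
        assert 30.0 < pair.gyr_thresh <= 85.0
        # grid-search oracle confirms a zero-cost region exists
        _, grid_best = grid_min_cost(db, UB, config)
        assert grid_best.num_errors == 0

    def test_optimizer_never_worse_than_grid(self, small_cohort):
        db = [t for ts in small_cohort.values() for t in ts]
        for criterion in ("angle_only", "gyro_only", "combined"):
            config = TrainingConfig(criterion=criterion, optimizer_seed=1)
            _, opt = optimize_thresholds(db, UB, config)
            _, grid = grid_min_cost(db, UB, config)
            assert opt.num_errors <= grid.num_errors

    def test_zero_weights_give_zero_cost(self, small_cohort):
        db = [t for ts in small_cohort.values() for t in ts][:10]
        config = TrainingConfig(
            criterion="combined", error_weights=(0.0, 0.0, 0.0), optimizer_seed=2
        )
        _, best = optimize_thresholds(db, UB, config)
        assert best.num_errors == 0

    def test_deterministic_given_seed(self, small_cohort):
        db = [t for ts in small_cohort.values() for t in ts][:12]
        config = TrainingConfig(criterion="combined", optimizer_seed=11)
        first = optimize_thresholds(db, UB, config)
        second = optimize_thresholds(db, UB, config)
        assert first == second

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            optimize_thresholds([], UB, TrainingConfig())
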