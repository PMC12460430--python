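import math

import numpy as np
import pytest

from traceddm.measures import (
    MEASURE_NAMES,
    MeasureConfig,
    aggregate,
    compute_all,
    count_measures,
    deviation_measures,
    kinematic_measures,
    sample_entropy,
    sample_entropy_x,
    trial_measures_frame,
)
from traceddm.trajectories import Trajectory, kinematics


def _traj(t, x, y):
    return Trajectory(t=np.asarray(t, float), x=np.asarray(x, float),
                      y=np.asarray(y, float))


def brute_force_sampen(z, m, r):
    """Literal O(n^2) template comparison, written independently."""
    z = np.asarray(z, float)
    n = len(z)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if all(abs(z[i + k] - z[j + k]) <= r for k in range(m)):
                b += 1
                if abs(z[i + m] - z[j + m]) <= r:
                    a += 1
    if b == 0 or a == 0:
        return float("nan")
    return -math.log(a / b)


class TestDeviationMeasures:
    def test_straight_path_is_degenerate_zero(self):
        n = 10
        traj = _traj(np.arange(n) * 0.1, -10.0 * np.arange(n),
                     10.0 * np.arange(n))
        d = deviation_measures(traj)
        for key in ("AD", "AUC", "MAD", "MADabove"):
            assert d[key] == pytest.approx(0.0, abs=1e-9)
        assert d["curvature"] == pytest.approx(1.0)

    def test_right_angle_path(self):
        traj = _traj([0, 0.5, 1.0], [0, 0, -100], [0, 100, 100])
        d = deviation_measures(traj)
        assert d["curvature"] == pytest.approx(200 / (100 * math.sqrt(2)))
        assert d["MAD"] == pytest.approx(100 / math.sqrt(2), abs=1e-6)
        # the up-then-left corner deviates toward the non-chosen side
        assert d["MADabove"] == pytest.approx(d["MAD"])

    def test_one_sided_path_has_zero_madabove(self):
        # bulge toward the chosen (left) side only
        traj = _traj([0, 0.5, 1.0], [0, -100, -100], [0, 0, 100])
        d = deviation_measures(traj)
        assert d["MADabove"] == 0.0
        assert d["MAD"] > 0

    def test_minx_is_closest_approach_to_alternative(self):
        traj = _traj([0, 0.3, 0.6, 1.0], [0, 12, -40, -80], [0, 30, 60, 90])
        assert deviation_measures(traj)["minX"] == pytest.approx(12.0)

    def test_zero_chord_raises(self):
        traj = _traj([0, 0.5, 1.0], [0, -50, 0], [0, 50, 0])
        with pytest.raises(ValueError, match="chord"):
            deviation_measures(traj)


class TestKinematicMeasures:
    def test_first_maximum_rule(self):
        # speeds 10, 30, 30, 20 px/s at t_mid 0.1..0.4 -> first max at 0.2
        x = np.cumsum([0, 1, 3, 3, 2])
        traj = _traj(np.arange(5) * 0.1, -x, np.zeros(5))
        m = kinematic_measures(traj)
        assert m["maxVel"] == pytest.approx(30.0)
        assert m["timeToPeakVel"] == pytest.approx(0.2)
        assert m["minVel"] == pytest.approx(10.0)
        assert m["motorPauses"] == 0.0

    def test_frozen_gap_counts_as_pause(self):
        t = [0, 0.1, 0.2, 0.4, 0.5]
        x = [0, -10, -10, -10, -30]
        traj = _traj(t, x, np.zeros(5))
        m = kinematic_measures(traj)
        assert m["motorPauses"] == pytest.approx(0.3)
        assert m["motionTime"] == pytest.approx(0.2)

    def test_mean_velocity_time_weighted(self):
        traj = _traj([0, 1.0, 1.5], [0, -10, -40], [0, 0, 0])
        m = kinematic_measures(traj)
        assert m["meanVel"] == pytest.approx(40 / 1.5)


class TestCountMeasures:
    def test_xflips_skips_zero_runs(self):
        traj = _traj(np.arange(5) * 0.1, [0, -1, -2, -1, -3], np.zeros(5))
        assert count_measures(traj)["xFlips"] == 2

    def test_reversals_crossings(self):
        traj = _traj(np.arange(4) * 0.1, [0, -5, 3, -2], np.arange(4.0))
        assert count_measures(traj)["reversals"] == 2

    def test_touch_and_return_counts_once(self):
        traj = _traj(np.arange(4) * 0.1, [0, -5, 0, -5], np.arange(4.0))
        assert count_measures(traj)["reversals"] == 1

    def test_monotone_constant_speed_has_no_events(self):
        traj = _traj(np.arange(6) * 0.1, -10.0 * np.arange(6), np.zeros(6))
        c = count_measures(traj)
        assert c["xFlips"] == 0
        assert c["accChanges"] == 0


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        traj = _traj(np.arange(10) * 0.1, np.full(10, 3.0), np.arange(10.0))
        assert sample_entropy_x(traj) == pytest.approx(0.0)

    def test_toy_alternating_series_matches_oracle(self):
        z = [1, 2, 1, 2, 1, 2, 1, 2]
        got = sample_entropy(np.array(z, float), m=2, r=0.5)
        want = brute_force_sampen(z, 2, 0.5)
        assert got == pytest.approx(want)

    @pytest.mark.parametrize("n", [8, 15, 30])
    def test_matches_brute_force_on_random_series(self, n, rng):
        for _ in range(20):
            z = rng.normal(size=n)
            r = 0.2 * z.std()
            got = sample_entropy(z, m=2, r=r)
            want = brute_force_sampen(z, 2, r)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_white_noise_more_complex_than_sine(self, rng):
        n = 120
        diffs = []
        for _ in range(100):
            noise = rng.normal(size=n)
            sine = np.sin(2 * np.pi * 3 * np.arange(n) / n)
            diffs.append(
                sample_entropy(noise, 2) - sample_entropy(sine, 2)
            )
        assert np.nanmedian(diffs) > 0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), m=2)


class TestInvariantsOnRandomWalks:
    def test_geometric_and_timing_invariants(self, rng):
        for _ in range(200):
            n = rng.integers(10, 60)
            t = np.cumsum(rng.uniform(0.005, 0.015, n))
            t -= t[0]
            x = np.cumsum(rng.normal(-1, 4, n))
            x -= x[0]
            y = np.cumsum(rng.uniform(0, 5, n))
            traj = Trajectory(t=t, x=x, y=y)
            d = deviation_measures(traj)
            k = kinematic_measures(traj)
            assert d["curvature"] >= 1.0 - 1e-12
            assert d["MADabove"] <= d["MAD"] + 1e-12
            assert k["minVel"] <= k["meanVel"] <= k["maxVel"] + 1e-9
            assert 0 <= k["timeToPeakVel"] <= traj.duration + 1e-12
            assert k["motorPauses"] + k["motionTime"] == pytest.approx(
                traj.duration, abs=1e-9
            )

    def test_all_measures_invariant_to_mirroring(self, rng, small_cohort):
        trials, _ = small_cohort
        recs = trials.trials[trials.participants[0]][:10]
        cfg = MeasureConfig()
        for rec in recs:
            base = compute_all(rec, cfg)
            mirrored = Trajectory(t=rec.trajectory.t, x=-rec.trajectory.x,
                                  y=rec.trajectory.y)
            flipped_side = "right" if rec.response_side == "left" else "left"
            from dataclasses import replace
            rec2 = replace(rec, trajectory=mirrored,
                           response_side=flipped_side,
                           stimulus_side="right" if rec.stimulus_side == "left"
                           else "left")
            other = compute_all(rec2, cfg)
            for name in MEASURE_NAMES:
                assert other[name] == pytest.approx(base[name], rel=1e-9), name


class TestAggregation:
    def test_single_trial_participant_mean_is_the_trial(self, small_cohort):
        trials, _ = small_cohort
        pid = trials.participants[0]
        from traceddm.trajectories import TrialSet
        one = TrialSet({pid: trials.trials[pid][:1]})
        per_trial = trial_measures_frame(one)
        agg = aggregate(one)
        for name in MEASURE_NAMES:
            assert agg[name].iloc[0] == pytest.approx(per_trial[name].iloc[0])

    def test_cohort_has_no_missing_cells(self, participant_table):
        assert not participant_table[MEASURE_NAMES].isna().any().any()
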