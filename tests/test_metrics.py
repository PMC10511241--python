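import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nucleotrack as nt
from conftest import make_trajectory


class TestComputeSteps:
    def test_345_triangle(self):
        t = make_trajectory([0.0, 3.0], [0.0, 4.0])
        s = nt.compute_steps(t)
        assert s.dx[0] == 3.0 and s.dy[0] == 4.0
        assert s.r_step[0] == pytest.approx(5.0)
        assert len(s.angles) == 0

    def test_left_turn_is_plus_90(self):
        t = make_trajectory([0.0, 1.0, 1.0], [0.0, 0.0, 1.0])  # steps (1,0) then (0,1)
        s = nt.compute_steps(t)
        assert s.angles[0] == pytest.approx(90.0)

    def test_reversal_is_180(self):
        t = make_trajectory([0.0, 1.0, 0.0], [0.0, 0.0, 0.0])  # steps (1,0) then (-1,0)
        s = nt.compute_steps(t)
        assert s.angles[0] == pytest.approx(180.0)

    def test_rstep_identity_and_counts(self, rng):
        pos = rng.normal(size=(20, 2))
        t = make_trajectory(pos[:, 0], pos[:, 1])
        s = nt.compute_steps(t)
        np.testing.assert_allclose(s.r_step**2, s.dx**2 + s.dy**2, rtol=1e-12)
        assert len(s.r_step) == len(t) - 1
        assert len(s.angles) == len(s.r_step) - 1

    def test_gap_raises(self):
        t = nt.Trajectory("t", "v", "c", [0, 1, 3], [0.0, 2.0, 6.0], [0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        with pytest.raises(nt.DataError):
            nt.compute_steps(t)


def brute_force_msd(positions, dt):
    """Double-loop time-averaged MSD: the straightforward definition."""
    n = len(positions)
    lags, msd = [], []
    for k in range(1, n):
        sq = [np.sum((positions[i + k] - positions[i]) ** 2) for i in range(n - k)]
        lags.append(k * dt)
        msd.append(np.mean(sq))
    return np.array(lags), np.array(msd)


class TestComputeMSD:
    def test_linear_track(self):
        t = make_trajectory([0.0, 1.0, 2.0, 3.0], np.zeros(4))
        curve = nt.compute_msd(t)
        np.testing.assert_allclose(curve.lags, [2.0, 4.0, 6.0])
        np.testing.assert_allclose(curve.msd, [1.0, 4.0, 9.0])
        np.testing.assert_array_equal(curve.n_pairs, [3, 2, 1])

    def test_stationary_is_zero(self):
        t = make_trajectory(np.full(10, 2.0), np.full(10, -1.0))
        curve = nt.compute_msd(t)
        np.testing.assert_array_equal(curve.msd, 0.0)

    def test_max_lag_truncates(self):
        t = make_trajectory(np.arange(10.0), np.zeros(10))
        curve = nt.compute_msd(t, max_lag=6.0)
        assert curve.lags[-1] == 6.0

    def test_max_lag_below_interval_rejected(self):
        t = make_trajectory(np.arange(4.0), np.zeros(4))
        with pytest.raises(nt.ParameterError):
            nt.compute_msd(t, max_lag=1.0)

    def test_matches_brute_force_on_random_tracks(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            pos = rng.normal(size=(n, 2)) * 3.0
            t = make_trajectory(pos[:, 0], pos[:, 1])
            curve = nt.compute_msd(t)
            lags, msd = brute_force_msd(pos, 2.0)
            np.testing.assert_allclose(curve.lags, lags)
            np.testing.assert_allclose(curve.msd, msd, rtol=1e-12)


class TestAverageMSD:
    def test_identical_curves(self):
        t = make_trajectory(np.arange(5.0), np.zeros(5))
        c = nt.compute_msd(t)
        avg = nt.average_msd([c, c])
        np.testing.assert_allclose(avg.msd, c.msd)
        np.testing.assert_allclose(avg.se, 0.0, atol=1e-15)

    def test_mean_and_se_of_two_values(self):
        a = nt.MSDCurve([2.0], [2.0], [1], [np.nan])
        b = nt.MSDCurve([2.0], [4.0], [1], [np.nan])
        avg = nt.average_msd([a, b])
        assert avg.msd[0] == pytest.approx(3.0)
        assert avg.se[0] == pytest.approx(1.0)
        assert avg.n_pairs[0] == 2

    def test_ragged_lengths_counted_per_lag(self):
        t1 = make_trajectory(np.arange(3.0), np.zeros(3))
        t2 = make_trajectory(np.arange(6.0), np.zeros(6))
        avg = nt.average_msd([nt.compute_msd(t1), nt.compute_msd(t2)])
        assert avg.n_pairs[0] == 2 and avg.n_pairs[-1] == 1

    def test_empty_rejected(self):
        with pytest.raises(nt.ParameterError):
            nt.average_msd([])


class TestEstimateDiffusion:
    def test_two_point_formula(self):
        curve = nt.MSDCurve([2.0, 4.0], [8.0, 16.0], [2, 1], [np.nan, np.nan])
        d = nt.estimate_diffusion(curve, dimensionality=2)
        assert d.value == pytest.approx(1.0)

    def test_missing_lags_rejected(self):
        curve = nt.MSDCurve([2.0], [8.0], [2], [np.nan])
        with pytest.raises(nt.EstimationError):
            nt.estimate_diffusion(curve)

    def test_mean_of_per_trajectory_equals_d_of_average_msd(self, brownian_trajectories):
        trajs = brownian_trajectories[:100]
        per = nt.metrics.diffusion_per_trajectory(trajs)
        from_avg = nt.estimate_diffusion(nt.average_msd([nt.compute_msd(t) for t in trajs]))
        assert per.mean() == pytest.approx(from_avg.value, rel=1e-9)

    def test_brownian_recovery_within_10pct(self, brownian_trajectories):
        est = nt.mean_diffusion(brownian_trajectories)
        assert est.value == pytest.approx(2.5, rel=0.10)

    def test_noise_offset_cancels(self, rng):
        # static localization noise adds a constant to every MSD lag; the
        # two-point slope is unaffected in expectation
        p_clean = nt.MotionParams(d1=1.0, d2=1.0, k12=0.0, k21=0.0, loc_noise_sd=0.0)
        p_noisy = nt.MotionParams(d1=1.0, d2=1.0, k12=0.0, k21=0.0, loc_noise_sd=1.0)
        clean = nt.mean_diffusion([nt.simulate_trajectory(p_clean, 60, s)[0] for s in range(400)])
        noisy = nt.mean_diffusion([nt.simulate_trajectory(p_noisy, 60, s + 1000)[0] for s in range(400)])
        assert noisy.value == pytest.approx(clean.value, abs=3 * (clean.se + noisy.se))


class TestAxisDiffusion:
    def test_isotropy_of_brownian(self, brownian_trajectories):
        dx = nt.axis_diffusion(brownian_trajectories, "x")
        dy = nt.axis_diffusion(brownian_trajectories, "y")
        # both axes estimate the same D; difference within joint 3 SE
        assert abs(dx.value - dy.value) < 3 * np.hypot(dx.se, dy.se)

    def test_axis_decomposition_identity(self, brownian_trajectories):
        trajs = brownian_trajectories[:50]
        dx = nt.axis_diffusion(trajs, "x").value
        dy = nt.axis_diffusion(trajs, "y").value
        d2 = nt.mean_diffusion(trajs).value
        assert dx + dy == pytest.approx(2.0 * d2, rel=1e-9)

    def test_1d_motion_noise_floor_on_other_axis(self, rng):
        # motion along x only; y shows just the localization-noise floor,
        # and the two-point estimator cancels it in expectation
        n = 60
        sd = 0.3
        trajs = []
        for i in range(200):
            x = np.cumsum(rng.normal(0, 2.0, n))
            y = rng.normal(0, sd, n)
            trajs.append(make_trajectory(x, y, trajectory_id=f"t{i}"))
        dy = nt.axis_diffusion(trajs, "y")
        assert abs(dy.value) < 3 * dy.se + 1e-3


class TestSummaries:
    def test_constant_steps(self):
        t = make_trajectory([0.0, 2.0, 4.0, 6.0, 8.0], np.zeros(5))
        rec = nt.trajectory_summary(t)
        assert rec["avg_step_nm"] == pytest.approx(2.0)
        assert rec["max_rstep_nm"] == pytest.approx(2.0)
        assert rec["rstep_var_nm2"] == pytest.approx(0.0)

    def test_accumulated_distance(self):
        t = make_trajectory([0.0, 3.0, 3.0], [0.0, 0.0, 4.0])  # steps 3 then 4
        rec = nt.trajectory_summary(t)
        assert rec["accumulated_distance_nm"] == pytest.approx(7.0)

    def test_single_trajectory_summary_has_undefined_se(self):
        t = make_trajectory(np.arange(12.0), np.zeros(12))
        rec = nt.condition_summary([t], condition="solo")
        assert rec["n_trajectories"] == 1
        assert np.isnan(rec["d_se_nm2_per_s"])

    def test_empty_condition_rejected(self):
        with pytest.raises(nt.ParameterError):
            nt.condition_summary([])

    def test_known_d_recovered_in_summary(self, brownian_trajectories):
        rec = nt.condition_summary(brownian_trajectories, condition="sim")
        ci = 3 * rec["d_se_nm2_per_s"]
        assert abs(rec["d_mean_nm2_per_s"] - 2.5) < ci


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    shift=st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
    theta=st.floats(0, 2 * np.pi),
)
def test_translation_and_rotation_invariance(seed, shift, theta):
    """2D statistics are unchanged by global translation and rotation."""
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.normal(0, 2.0, size=(15, 2)), axis=0)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = pos @ rot.T + np.asarray(shift)
    a = make_trajectory(pos[:, 0], pos[:, 1])
    b = make_trajectory(moved[:, 0], moved[:, 1])
    np.testing.assert_allclose(
        nt.compute_steps(b).r_step, nt.compute_steps(a).r_step, rtol=1e-9, atol=1e-9
    )
    np.testing.assert_allclose(nt.compute_msd(b).msd, nt.compute_msd(a).msd, rtol=1e-9, atol=1e-9)
    ra, rb = nt.trajectory_summary(a), nt.trajectory_summary(b)
    assert rb["d_nm2_per_s"] == pytest.approx(ra["d_nm2_per_s"], rel=1e-9, abs=1e-12)
    assert rb["extent_nm"] == pytest.approx(ra["extent_nm"], rel=1e-9)
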