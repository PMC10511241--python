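import numpy as np
import pytest

import nucleotrack as nt
from nucleotrack.preprocess import (
    STATUS_ACCEPTED,
    STATUS_STEP_EXCEEDED,
    STATUS_STUCK,
    STATUS_TOO_SHORT,
    STATUS_TRUNCATED,
)
from conftest import make_trajectory


def one_fps_video(n_frames=10, n_traj=2):
    """Video at the raw 1 s scan rate (frame_interval=1)."""
    trajs = [
        make_trajectory(
            np.arange(n_frames, dtype=float) + i,
            np.zeros(n_frames),
            frame_interval=1.0,
            trajectory_id=f"t{i}",
        )
        for i in range(n_traj)
    ]
    return nt.VideoDataset("v0", "test", 1.0, trajs)


class TestDecimation:
    def test_halves_frames_and_doubles_interval(self):
        out = nt.decimate_frames(one_fps_video(10))
        assert out.frame_interval == 2.0
        for t in out.trajectories:
            assert len(t) == 5
            np.testing.assert_allclose(t.times, t.frames * 2.0)

    def test_double_decimation_quarters_frames(self):
        once = nt.decimate_frames(one_fps_video(8))
        twice = nt.decimate_frames(once)
        assert all(len(t) == 2 for t in twice.trajectories)

    def test_single_frame_remnant_dropped(self):
        video = one_fps_video(3)  # odd parity keeps only frame 1
        out = nt.decimate_frames(video, keep_parity="odd")
        assert len(out) == 0

    def test_parity_selects_frames(self):
        video = one_fps_video(6)
        even = nt.decimate_frames(video, keep_parity="even")
        odd = nt.decimate_frames(video, keep_parity="odd")
        np.testing.assert_allclose(even.trajectories[0].x, [0.0, 2.0, 4.0])
        np.testing.assert_allclose(odd.trajectories[0].x, [1.0, 3.0, 5.0])


class TestDriftEstimation:
    def test_pure_translation_recovered_exactly(self):
        # all particles move (+1, 0) per frame with no intrinsic motion
        n = 8
        trajs = [
            make_trajectory(np.arange(n, dtype=float), np.full(n, float(i)), trajectory_id=f"t{i}")
            for i in range(5)
        ]
        video = nt.VideoDataset("v0", "test", 2.0, trajs)
        drift = nt.estimate_drift(video)
        np.testing.assert_allclose(drift.dx, np.arange(n, dtype=float), atol=1e-12)
        np.testing.assert_allclose(drift.dy, 0.0, atol=1e-12)

    def test_injected_drift_recovered_within_5pct(self):
        # estimator error on the cumulative drift vector scales as
        # sqrt((2 D dt + 2 sigma^2) * n_frames / n_particles); a dense video
        # of moderate mobility puts that well below the 5% tolerance
        p = nt.MotionParams(
            d1=1.0, d2=1.0, k12=0.0, k21=0.0, drift_velocity=(0.5, -0.25),
            loc_noise_sd=0.3, n_frames_range=(60, 60),
        )
        video, gt = nt.simulate_video(p, 200, seed=10)
        drift = nt.estimate_drift(video)
        est = np.array([drift.dx[-1], drift.dy[-1]])
        err = np.linalg.norm(est - gt.drift[-1]) / np.linalg.norm(gt.drift[-1])
        assert err < 0.05

    def test_stationary_particle_noise_floor(self):
        # with one stuck particle (noise sd 0.1 nm) the per-frame drift
        # increment is a mean of one N(0, 2*0.1^2) difference: |increment|
        # rarely exceeds ~3 sd = 0.42 nm
        p = nt.MotionParams(stuck_fraction=1.0, loc_noise_sd=0.1, n_frames_range=(60, 60))
        video, _ = nt.simulate_video(p, 1, seed=3)
        drift = nt.estimate_drift(video)
        increments = np.hypot(np.diff(drift.dx), np.diff(drift.dy))
        assert np.quantile(increments, 0.95) < 0.42

    def test_no_shared_frame_pairs_is_estimation_error(self):
        # two particles on interleaved frames: no particle spans any
        # consecutive observed frame pair
        t1 = nt.Trajectory("a", "v0", "test", [0, 2], [0.0, 4.0], [0.0, 1.0], [0.0, 0.0])
        t2 = nt.Trajectory("b", "v0", "test", [1, 3], [2.0, 6.0], [0.0, 1.0], [0.0, 0.0])
        video = nt.VideoDataset("v0", "test", 2.0, [t1, t2])
        with pytest.raises(nt.EstimationError):
            nt.estimate_drift(video)


class TestDriftCorrection:
    def test_zero_model_is_identity(self):
        video, _ = nt.simulate_video(nt.MotionParams(), 5, seed=1)
        frames = video.all_frames
        zero = nt.DriftModel("video", frames, np.zeros(len(frames)), np.zeros(len(frames)))
        out = nt.apply_drift_correction(video, zero)
        for a, b in zip(video.trajectories, out.trajectories):
            np.testing.assert_array_equal(a.x, b.x)

    def test_residual_drift_under_5pct_of_injected(self):
        p = nt.MotionParams(
            d1=1.0, d2=1.0, k12=0.0, k21=0.0, drift_velocity=(0.5, -0.25),
            loc_noise_sd=0.3, n_frames_range=(60, 60),
        )
        video, gt = nt.simulate_video(p, 200, seed=12)
        corrected = nt.apply_drift_correction(video, nt.estimate_drift(video))
        residual = nt.estimate_drift(corrected)
        injected = np.hypot(*gt.drift[-1])
        assert np.hypot(residual.dx[-1], residual.dy[-1]) < 0.05 * injected

    def test_double_correction_shifts_twice(self):
        video, _ = nt.simulate_video(nt.MotionParams(drift_velocity=(0.4, 0.0)), 20, seed=5)
        drift = nt.estimate_drift(video)
        once = nt.apply_drift_correction(video, drift)
        twice = nt.apply_drift_correction(once, drift)
        for v, o, t in zip(video.trajectories, once.trajectories, twice.trajectories):
            np.testing.assert_allclose(v.x - t.x, 2.0 * (v.x - o.x), atol=1e-9)

    def test_missing_frame_is_coverage_error(self):
        video, _ = nt.simulate_video(nt.MotionParams(n_frames_range=(20, 20)), 3, seed=1)
        short = nt.DriftModel("video", np.arange(10), np.zeros(10), np.zeros(10))
        with pytest.raises(nt.CoverageError):
            nt.apply_drift_correction(video, short)


def brute_force_qc(traj, rules):
    """Independent re-statement of the selection rules, in rule-text order."""
    if len(traj) < rules.min_points:
        return STATUS_TOO_SHORT
    truncated = len(traj) > rules.max_points
    x = traj.x[: rules.max_points]
    y = traj.y[: rules.max_points]
    r = [np.sqrt((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2) for i in range(len(x) - 1)]
    if max(r) > rules.max_step_nm:
        return STATUS_STEP_EXCEEDED
    extent = max(
        np.sqrt((x[i] - x[j]) ** 2 + (y[i] - y[j]) ** 2)
        for i in range(len(x))
        for j in range(len(x))
    )
    if (sum(r) / len(r) < rules.stuck_avg_rstep_nm) and (extent < rules.stuck_extent_nm):
        return STATUS_STUCK
    return STATUS_TRUNCATED if truncated else STATUS_ACCEPTED


def random_qc_population(n, seed):
    """Trajectories spanning all QC regimes: short, long, stuck, jumpy, mobile."""
    rng = np.random.default_rng(seed)
    trajs = []
    for i in range(n):
        kind = rng.integers(0, 5)
        n_frames = int(rng.integers(3, 9)) if kind == 0 else int(rng.integers(10, 90))
        if kind == 1:  # stuck-like
            sd = 0.2
        elif kind == 2:  # occasionally jumpy
            sd = 8.0
        else:
            sd = float(rng.uniform(0.5, 4.0))
        steps = rng.normal(0.0, sd, size=(n_frames - 1, 2))
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        trajs.append(
            make_trajectory(pos[:, 0], pos[:, 1], trajectory_id=f"t{i}")
        )
    return nt.VideoDataset("v0", "test", 2.0, trajs)


class TestQCFilter:
    def test_nine_points_too_short(self):
        t = make_trajectory(np.linspace(0, 16, 9), np.zeros(9))
        res = nt.qc_filter(nt.VideoDataset("v0", "test", 2.0, [t]))
        assert res.decisions[0].status == STATUS_TOO_SHORT

    def test_single_25nm_step_rejected(self):
        x = np.linspace(0, 20, 15).tolist()
        x[7] = x[6] + 25.0  # one oversized step
        x[8:] = [x[7] + 1.0 * k for k in range(1, 8)]
        t = make_trajectory(x, np.zeros(15))
        res = nt.qc_filter(nt.VideoDataset("v0", "test", 2.0, [t]))
        assert res.decisions[0].status == STATUS_STEP_EXCEEDED

    def test_small_slow_trajectory_is_stuck(self):
        rng = np.random.default_rng(0)
        steps = rng.normal(0.0, 0.3, size=(29, 2))  # avg R-step ~0.5 nm
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        t = make_trajectory(pos[:, 0], pos[:, 1])
        res = nt.qc_filter(nt.VideoDataset("v0", "test", 2.0, [t]))
        d = res.decisions[0]
        assert d.status == STATUS_STUCK
        assert d.avg_rstep_nm < 1.0 and d.extent_nm < 8.0

    def test_long_trajectory_truncated_and_retained(self):
        rng = np.random.default_rng(1)
        steps = rng.normal(0.0, 2.0, size=(89, 2))
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        t = make_trajectory(pos[:, 0], pos[:, 1])
        res = nt.qc_filter(nt.VideoDataset("v0", "test", 2.0, [t]))
        assert res.decisions[0].status == STATUS_TRUNCATED
        assert len(res.accepted) == 1
        assert len(res.accepted[0]) == 60

    def test_partition_property(self):
        video = random_qc_population(300, seed=2)
        res = nt.qc_filter(video)
        assert len(res.accepted) + len(res.stuck) + len(res.rejected) == len(video)
        ids = [t.trajectory_id for t in res.accepted + res.stuck + res.rejected]
        assert len(set(ids)) == len(video)

    def test_matches_brute_force_oracle_on_1000_trajectories(self):
        video = random_qc_population(1000, seed=7)
        rules = nt.QCRules()
        res = nt.qc_filter(video, rules)
        expected = {t.trajectory_id: brute_force_qc(t, rules) for t in video.trajectories}
        for d in res.decisions:
            assert d.status == expected[d.trajectory_id], d.trajectory_id

    def test_loosening_max_step_is_monotone(self):
        video = random_qc_population(300, seed=3)
        strict = {d.trajectory_id: d.status for d in nt.qc_filter(video, nt.QCRules(max_step_nm=12.0)).decisions}
        loose = {d.trajectory_id: d.status for d in nt.qc_filter(video, nt.QCRules(max_step_nm=30.0)).decisions}
        for tid, s in strict.items():
            if s != STATUS_STEP_EXCEEDED:
                assert loose[tid] == s  # only step_exceeded decisions may change

    def test_stuck_fraction_recovered(self):
        p = nt.MotionParams(d1=0.5, d2=4.0, stuck_fraction=0.25, loc_noise_sd=0.2,
                            n_frames_range=(15, 60))
        video, _ = nt.simulate_video(p, 200, seed=21)
        res = nt.qc_filter(video)
        assert len(res.stuck) / len(video) == pytest.approx(0.25, abs=0.05)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(nt.ParameterError):
            nt.QCRules(max_step_nm=0.0)
        with pytest.raises(nt.ParameterError):
            nt.QCRules(min_points=12, max_points=10)
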