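"""Seeded simulation studies that verify the pipeline end to end.

Each study generates data with the synthetic generator under stated
conditions, runs the estimator under test, and returns the measured
quantities together with the ground truth it should recover. The studies
double as reproducible benchmarks: the test suite asserts on their outputs
and the acceptance script reports them.

All randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .diagnostics import angle_uniformity_test, axis_bias_test, stepsize_vs_time_test
from .io import Trajectory
from .metrics import (
    average_msd,
    compute_msd,
    compute_steps,
    estimate_diffusion,
    mean_diffusion,
)
from .mixture import fit_step_mixture, select_mixture
from .preprocess import apply_drift_correction, estimate_drift, qc_filter
from .synthetic import MotionParams, simulate_trajectory, simulate_video


def _single_state(d: float, **kwargs) -> MotionParams:
    return MotionParams(d1=d, d2=d, k12=0.0, k21=0.0, loc_noise_sd=0.0, **kwargs)


def _ensemble(params: MotionParams, n: int, n_frames: int, rng) -> list[Trajectory]:
    return [
        simulate_trajectory(params, n_frames, rng, trajectory_id=f"t{i}")[0] for i in range(n)
    ]


def brownian_msd_study(
    seed: int,
    d: float = 2.5,
    n_trajectories: int = 500,
    n_frames: int = 60,
    n_lags: int = 5,
) -> dict:
    """Free 2D diffusion: ensemble MSD against the closed form 4·D·τ.

    Also evaluates the two-point diffusion estimator and the exact identity
    between the mean of per-trajectory estimates and the estimate from the
    averaged MSD curve.
    """
    rng = np.random.default_rng(seed)
    trajs = _ensemble(_single_state(d), n_trajectories, n_frames, rng)
    avg = average_msd([compute_msd(t) for t in trajs])
    expected = 4.0 * d * avg.lags
    rel_err = np.abs(avg.msd[:n_lags] / expected[:n_lags] - 1.0)
    mean_est = mean_diffusion(trajs)
    from_avg = estimate_diffusion(avg)
    return {
        "true_d": d,
        "lags_s": avg.lags[:n_lags],
        "msd_nm2": avg.msd[:n_lags],
        "expected_msd_nm2": expected[:n_lags],
        "msd_max_rel_err": float(rel_err.max()),
        "mean_d": mean_est.value,
        "mean_d_se": mean_est.se,
        "d_from_average_msd": from_avg.value,
        "identity_rel_err": abs(mean_est.value - from_avg.value) / abs(from_avg.value),
        "n": n_trajectories,
    }


def drift_recovery_study(
    seed: int,
    velocity: tuple[float, float] = (0.5, -0.25),
    d: float = 1.0,
    loc_noise_sd: float = 0.3,
    n_particles: int = 200,
    n_frames: int = 60,
) -> dict:
    """Recover a shared linear stage drift from a dense simulated video.

    The estimator error on the cumulative drift vector scales as
    sqrt((2·D·Δt + 2·σ²)·n_frames / n_particles), so particle count and
    mobility set the attainable accuracy.
    """
    params = MotionParams(
        d1=d, d2=d, k12=0.0, k21=0.0, drift_velocity=velocity,
        loc_noise_sd=loc_noise_sd, n_frames_range=(n_frames, n_frames),
    )
    video, truth = simulate_video(params, n_particles, seed)
    model = estimate_drift(video)
    est = np.array([model.dx[-1], model.dy[-1]])
    true = truth.drift[-1]
    recovery_rel_err = float(np.linalg.norm(est - true) / np.linalg.norm(true))
    corrected = apply_drift_correction(video, model)
    residual = estimate_drift(corrected)
    res = np.array([residual.dx[-1], residual.dy[-1]])
    return {
        "true_cumulative_nm": true,
        "estimated_cumulative_nm": est,
        "recovery_rel_err": recovery_rel_err,
        "residual_frac_of_injected": float(np.linalg.norm(res) / np.linalg.norm(true)),
        "n": n_particles,
    }


def mixture_recovery_study(
    seed: int,
    f1: float = 0.4,
    d1: float = 0.2,
    d2: float = 4.0,
    n_steps: int = 20_000,
    frame_interval: float = 2.0,
) -> dict:
    """Fit a known two-state step mixture and run model selection."""
    rng = np.random.default_rng(seed)
    n1 = int(round(f1 * n_steps))
    steps = rng.permutation(
        np.concatenate(
            [
                rng.normal(0.0, np.sqrt(2.0 * d1 * frame_interval), n1),
                rng.normal(0.0, np.sqrt(2.0 * d2 * frame_interval), n_steps - n1),
            ]
        )
    )
    fit1 = fit_step_mixture(steps, 1, frame_interval, seed=seed)
    fit2 = fit_step_mixture(steps, 2, frame_interval, seed=seed)
    sel = select_mixture(fit1, fit2)
    return {
        "true_f1": f1,
        "true_d1": d1,
        "true_d2": d2,
        "f1_hat": float(fit2.weights[0]),
        "d1_hat": float(fit2.d_values[0]),
        "d2_hat": float(fit2.d_values[1]),
        "chosen_k": sel.chosen_k,
        "delta_bic": sel.delta_bic,
        "n": n_steps,
    }


def single_state_selection_study(
    seed: int, n_replicates: int = 100, n_steps: int = 2_000, sigma: float = 2.0
) -> dict:
    """Fraction of single-Gaussian datasets for which selection keeps k=1."""
    rng = np.random.default_rng(seed)
    k1 = 0
    for rep in range(n_replicates):
        steps = rng.normal(0.0, sigma, n_steps)
        fit1 = fit_step_mixture(steps, 1, 2.0)
        fit2 = fit_step_mixture(steps, 2, 2.0, seed=seed + rep)
        if select_mixture(fit1, fit2).chosen_k == 1:
            k1 += 1
    return {"k1_rate": k1 / n_replicates, "n": n_replicates}


def qc_partition_study(
    seed: int, stuck_fraction: float = 0.25, n_particles: int = 200
) -> dict:
    """Recover the stuck fraction of a mixed mobile/stuck population via QC."""
    params = MotionParams(
        d1=0.5, d2=4.0, stuck_fraction=stuck_fraction, loc_noise_sd=0.2,
        n_frames_range=(15, 60),
    )
    video, truth = simulate_video(params, n_particles, seed)
    res = qc_filter(video)
    stuck_ids = {t.trajectory_id for t in res.stuck}
    true_ids = set(truth.stuck_ids)
    return {
        "true_stuck_fraction": stuck_fraction,
        "stuck_fraction_hat": len(res.stuck) / len(video),
        "accepted_fraction": len(res.accepted) / len(video),
        "rejected_fraction": len(res.rejected) / len(video),
        "stuck_recall": len(stuck_ids & true_ids) / max(1, len(true_ids)),
        "n": n_particles,
    }


def confinement_plateau_study(
    seed: int,
    radius: float = 15.0,
    d: float = 3.0,
    n_trajectories: int = 100,
    n_frames: int = 300,
    window: tuple[float, float] = (80.0, 160.0),
) -> dict:
    """Average MSD plateau of reflecting-disc trajectories against R².

    The plateau is read in a lag window far above the disc mixing time
    (~R²/4D) yet far below the track length, where pairs anchored to the
    non-stationary start point are a negligible fraction.
    """
    rng = np.random.default_rng(seed)
    params = _single_state(d, confinement_radius=radius)
    trajs = _ensemble(params, n_trajectories, n_frames, rng)
    avg = average_msd([compute_msd(t) for t in trajs])
    mask = (avg.lags >= window[0]) & (avg.lags <= window[1])
    plateau = float(avg.msd[mask].mean())
    return {
        "radius_nm": radius,
        "plateau_nm2": plateau,
        "expected_nm2": radius**2,
        "rel_err": abs(plateau - radius**2) / radius**2,
        "n": n_trajectories,
    }


# ---------------------------------------------------------------------------
# diagnostics calibration and power
# ---------------------------------------------------------------------------


def _angle_replicate(rng, drift=(0.0, 0.0), n_traj=40, n_frames=51, d=2.0):
    params = MotionParams(
        d1=d, d2=d, k12=0.0, k21=0.0, loc_noise_sd=0.0, drift_velocity=drift
    )
    angles = [
        compute_steps(simulate_trajectory(params, n_frames, rng)[0]).angles
        for _ in range(n_traj)
    ]
    return angle_uniformity_test(np.concatenate(angles))


def _axis_replicate(rng, anisotropy=1.0, n_traj=100, n_frames=30, d=2.0):
    params = _single_state(d)
    dx, dy = [], []
    for i in range(n_traj):
        t, _ = simulate_trajectory(params, n_frames, rng)
        if anisotropy != 1.0:  # scale x so that D_x = anisotropy * D_y
            t = t.with_coords(t.x * np.sqrt(anisotropy), t.y)
        dx.append(estimate_diffusion(compute_msd(t, max_lag=4.0, coords="x"), 1).value)
        dy.append(estimate_diffusion(compute_msd(t, max_lag=4.0, coords="y"), 1).value)
    return axis_bias_test(dx, dy)


def _stepsize_replicate(rng, decay=0.0, n_traj=40, n_frames=40, sigma=2.0, dt=2.0):
    # per-axis step scale shrinking by `decay` fraction over the video models
    # mobility loss during imaging; decay 0 is the stationary null
    times = np.tile(np.arange(n_frames - 1) * dt, n_traj)
    scale = sigma * (1.0 - decay * times / times.max())
    r = np.hypot(rng.normal(0.0, scale), rng.normal(0.0, scale))
    return stepsize_vs_time_test(r, times)


_REPLICATES = {
    "angle": _angle_replicate,
    "axis": _axis_replicate,
    "stepsize": _stepsize_replicate,
}

_ALTERNATIVES = {
    "angle": {"drift": (1.5, 0.0)},  # strong uncorrected drift
    "axis": {"anisotropy": 2.0},  # D_x = 2 D_y
    "stepsize": {"decay": 0.5},  # step scale halves over the video
}


def diagnostic_rejection_rate(
    seed: int, test: str, n_replicates: int = 500, alternative: bool = False
) -> dict:
    """Rejection rate of one diagnostic under its null or designed alternative.

    Under the null the rate estimates the type-I error (nominal 0.05);
    under the alternative it estimates power.
    """
    if test not in _REPLICATES:
        raise ValueError(f"unknown diagnostic {test!r}")
    rng = np.random.default_rng(seed)
    kwargs = _ALTERNATIVES[test] if alternative else {}
    rejections = sum(_REPLICATES[test](rng, **kwargs).reject for _ in range(n_replicates))
    return {"test": test, "rate": rejections / n_replicates, "n": n_replicates}
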