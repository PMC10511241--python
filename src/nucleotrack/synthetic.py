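"""Seeded synthetic trajectory generator with known ground truth.

The generator reproduces the statistical structure the downstream analysis
assumes for surface-adsorbed nucleosomes imaged at a 2 s effective frame
interval: two diffusive states with distinct diffusion constants and
stochastic switching, optional confinement (reflecting circular boundary)
producing an MSD plateau, optional linear stage drift shared by all
particles of a video, isotropic white localization noise, and a
sub-population of near-immobile ("stuck") particles.

Per-axis displacement in state ``s`` over one frame is drawn zero-mean
Gaussian with variance ``2 * D_s * dt``, so the pooled step-displacement
distribution of a two-state population is a two-component zero-mean
Gaussian mixture — the model the mixture-fitting stage estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import Trajectory, VideoDataset

#: ground-truth state code for stuck (noise-only) particles
STUCK_STATE = 0


@dataclass(frozen=True)
class MotionParams:
    """Parameters of the two-state confined-diffusion motion model.

    Defaults describe a mobile nucleosome-array population at the effective
    2 s frame interval: a slow (paused) state near D1 = 0.2 nm²/s, a fast
    state near D2 = 4 nm²/s, stationary slow-state occupancy 0.4, and
    sub-nanometer localization noise.
    """

    d1: float = 0.2  # nm²/s, slow state (state 1)
    d2: float = 4.0  # nm²/s, fast state (state 2)
    k12: float = 0.15  # s⁻¹, switching rate state 1 → 2
    k21: float = 0.10  # s⁻¹, switching rate state 2 → 1
    confinement_radius: float | None = None  # nm; None = unconfined
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # nm/s
    loc_noise_sd: float = 0.5  # nm, per axis per frame
    stuck_fraction: float = 0.0  # fraction of particles that are noise-only
    frame_interval: float = 2.0  # s
    n_frames_range: tuple[int, int] = (10, 60)

    def __post_init__(self) -> None:
        vals = [self.d1, self.d2, self.k12, self.k21, self.loc_noise_sd, self.frame_interval]
        if not all(np.isfinite(v) for v in vals):
            raise ParameterError("motion parameters must be finite")
        if self.d1 < 0 or self.d2 < self.d1:
            raise ParameterError("require 0 <= d1 <= d2 (state 1 is the slower state)")
        if self.k12 < 0 or self.k21 < 0:
            raise ParameterError("switching rates must be >= 0")
        if self.confinement_radius is not None and self.confinement_radius <= 0:
            raise ParameterError("confinement_radius must be > 0 or None")
        if self.loc_noise_sd < 0:
            raise ParameterError("loc_noise_sd must be >= 0")
        if not 0.0 <= self.stuck_fraction <= 1.0:
            raise ParameterError("stuck_fraction must be in [0, 1]")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        lo, hi = self.n_frames_range
        if lo < 2 or hi < lo:
            raise ParameterError("n_frames_range must satisfy 2 <= lo <= hi")

    @property
    def occupancy(self) -> float:
        """Stationary fraction of state 1, k21/(k12+k21); 1.0 if both rates are 0."""
        total = self.k12 + self.k21
        return self.k21 / total if total > 0 else 1.0


@dataclass
class GroundTruth:
    """Simulation bookkeeping for parameter-recovery tests.

    ``states`` maps trajectory id to the per-frame state sequence
    (1 = slow, 2 = fast, 0 = stuck); its length equals the number of frames
    (steps + 1). ``drift`` holds the cumulative per-frame drift (nm) shared
    by the video, one row per frame.
    """

    params: MotionParams
    states: dict = field(default_factory=dict)
    drift: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    stuck_ids: list = field(default_factory=list)


def _sample_states(params: MotionParams, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Per-frame two-state Markov chain; switching checked once per frame."""
    dt = params.frame_interval
    p12 = 1.0 - np.exp(-params.k12 * dt)
    p21 = 1.0 - np.exp(-params.k21 * dt)
    states = np.empty(n_frames, dtype=np.int8)
    states[0] = 1 if rng.random() < params.occupancy else 2
    if p12 == 0.0 and p21 == 0.0:
        states[:] = states[0]
        return states
    u = rng.random(n_frames - 1)
    s = states[0]
    for i in range(1, n_frames):
        if s == 1:
            if u[i - 1] < p12:
                s = 2
        elif u[i - 1] < p21:
            s = 1
        states[i] = s
    return states


def _reflect_into_disc(positions: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Sequentially reflect each step at a circular boundary about ``center``.

    A position landing outside the disc is mirrored radially across the
    boundary (distance d maps to 2R - d), repeatedly if a single step
    overshoots more than one radius.
    """
    out = np.empty_like(positions)
    prev = positions[0] - center
    out[0] = positions[0]
    for i in range(1, len(positions)):
        p = prev + (positions[i] - positions[i - 1])
        d = float(np.hypot(p[0], p[1]))
        while d > radius:
            p = p * ((2.0 * radius - d) / d)
            d = abs(2.0 * radius - d)
        out[i] = p + center
        prev = p
    return out


def simulate_trajectory(
    params: MotionParams,
    n_frames: int,
    seed,
    trajectory_id: str = "traj",
    video_id: str = "video",
    condition: str = "synthetic",
    start: tuple[float, float] = (0.0, 0.0),
    stuck: bool = False,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one trajectory of ``n_frames`` positions.

    The intrinsic path is built first (state-dependent Gaussian increments,
    then confinement), then cumulative drift is added, then localization
    noise. ``seed`` may be an integer or a ``numpy.random.Generator``;
    identical (params, seed) gives identical output.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = params.frame_interval
    start = np.asarray(start, dtype=float)

    if stuck:
        states = np.full(n_frames, STUCK_STATE, dtype=np.int8)
        clean = np.tile(start, (n_frames, 1))
    else:
        states = _sample_states(params, n_frames, rng)
        sigma = np.where(states[:-1] == 1, np.sqrt(2.0 * params.d1 * dt), np.sqrt(2.0 * params.d2 * dt))
        increments = rng.standard_normal((n_frames - 1, 2)) * sigma[:, None]
        clean = start + np.vstack([np.zeros(2), np.cumsum(increments, axis=0)])
        if params.confinement_radius is not None:
            clean = _reflect_into_disc(clean, start, params.confinement_radius)

    frames = np.arange(n_frames, dtype=np.int64)
    drift = np.outer(frames * dt, np.asarray(params.drift_velocity, dtype=float))
    noisy = clean + drift
    if params.loc_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, params.loc_noise_sd, size=(n_frames, 2))

    traj = Trajectory(
        trajectory_id=trajectory_id,
        video_id=video_id,
        condition=condition,
        frames=frames,
        times=frames * dt,
        x=noisy[:, 0],
        y=noisy[:, 1],
    )
    truth = GroundTruth(
        params=params,
        states={trajectory_id: states},
        drift=drift,
        stuck_ids=[trajectory_id] if stuck else [],
    )
    return traj, truth


def simulate_video(
    params: MotionParams,
    n_particles: int,
    seed,
    video_id: str = "video",
    condition: str = "synthetic",
    field_size: float = 400.0,
) -> tuple[VideoDataset, GroundTruth]:
    """Simulate one video of ``n_particles`` trajectories sharing a drift series.

    Trajectory lengths are drawn uniformly from ``params.n_frames_range``;
    ``round(stuck_fraction * n_particles)`` randomly chosen particles are
    stuck (noise-only). Start positions are scattered uniformly over a
    ``field_size`` × ``field_size`` nm area, mirroring a scan window. All
    trajectories start at frame 0.
    """
    if n_particles < 1:
        raise ParameterError("n_particles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = params.n_frames_range
    lengths = rng.integers(lo, hi + 1, size=n_particles)
    n_stuck = int(round(params.stuck_fraction * n_particles))
    stuck_flags = np.zeros(n_particles, dtype=bool)
    stuck_flags[rng.permutation(n_particles)[:n_stuck]] = True
    starts = rng.uniform(0.0, field_size, size=(n_particles, 2))

    max_frames = int(lengths.max())
    dt = params.frame_interval
    drift = np.outer(np.arange(max_frames) * dt, np.asarray(params.drift_velocity, dtype=float))

    width = len(str(n_particles - 1))
    trajs, truth_states, stuck_ids = [], {}, []
    for i in range(n_particles):
        tid = f"{video_id}-t{i:0{width}d}"
        traj, tr = simulate_trajectory(
            params,
            int(lengths[i]),
            rng,
            trajectory_id=tid,
            video_id=video_id,
            condition=condition,
            start=tuple(starts[i]),
            stuck=bool(stuck_flags[i]),
        )
        trajs.append(traj)
        truth_states[tid] = tr.states[tid]
        if stuck_flags[i]:
            stuck_ids.append(tid)

    dataset = VideoDataset(
        video_id=video_id, condition=condition, frame_interval=dt, trajectories=trajs
    )
    truth = GroundTruth(params=params, states=truth_states, drift=drift, stuck_ids=stuck_ids)
    return dataset, truth


def simulate_condition(
    params: MotionParams,
    n_videos: int,
    n_particles: int,
    seed,
    condition: str = "synthetic",
) -> tuple[list[VideoDataset], list[GroundTruth]]:
    """Simulate ``n_videos`` independent videos of one condition."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    datasets, truths = [], []
    for v in range(n_videos):
        ds, gt = simulate_video(
            params, n_particles, rng, video_id=f"{condition}-v{v}", condition=condition
        )
        datasets.append(ds)
        truths.append(gt)
    return datasets, truths


def write_ground_truth(truth: GroundTruth, path) -> Path:
    """Write a ground-truth sidecar CSV: trajectory, frame, state, drift."""
    rows = []
    for tid in sorted(truth.states):
        states = truth.states[tid]
        n = len(states)
        rows.append(
            pd.DataFrame(
                {
                    "trajectory_id": tid,
                    "frame": np.arange(n, dtype=np.int64),
                    "true_state": states.astype(int),
                    "drift_x_nm": truth.drift[:n, 0],
                    "drift_y_nm": truth.drift[:n, 1],
                }
            )
        )
    path = Path(path)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    return path


def params_from_config(config: dict) -> MotionParams:
    """Build MotionParams from a config mapping, ignoring unknown keys."""
    keys = MotionParams.__dataclass_fields__.keys()
    kwargs = {k: config[k] for k in keys if k in config}
    if "drift_velocity" in kwargs:
        kwargs["drift_velocity"] = tuple(kwargs["drift_velocity"])
    if "n_frames_range" in kwargs:
        kwargs["n_frames_range"] = tuple(int(v) for v in kwargs["n_frames_range"])
    if kwargs.get("confinement_radius") in ("none", "None", ""):
        kwargs["confinement_radius"] = None
    return MotionParams(**kwargs)
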