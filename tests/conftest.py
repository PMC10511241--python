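import numpy as np
import pytest

from nucleotrack import MotionParams, simulate_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def brownian_params():
    """Single-state Brownian motion, no noise/drift/confinement."""
    return MotionParams(d1=2.5, d2=2.5, k12=0.0, k21=0.0, loc_noise_sd=0.0)


@pytest.fixture
def brownian_trajectories(brownian_params):
    """300 noise-free Brownian trajectories of 60 frames, D = 2.5 nm²/s."""
    return [
        simulate_trajectory(brownian_params, 60, seed, trajectory_id=f"t{seed}")[0]
        for seed in range(300)
    ]


def make_trajectory(x, y, frame_interval=2.0, trajectory_id="t0", video_id="v0"):
    """Build a Trajectory from raw coordinate lists."""
    from nucleotrack import Trajectory

    x = np.asarray(x, dtype=float)
    frames = np.arange(len(x))
    return Trajectory(
        trajectory_id=trajectory_id,
        video_id=video_id,
        condition="test",
        frames=frames,
        times=frames * frame_interval,
        x=x,
        y=np.asarray(y, dtype=float),
    )
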