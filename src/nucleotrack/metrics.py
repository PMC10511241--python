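"""Per-trajectory step series, MSD curves, diffusion constants, summaries.

The R-step is the planar single-frame displacement magnitude
``sqrt(dx² + dy²)``. MSD curves are time-averaged over all overlapping
pairs. The diffusion constant is the two-point slope of the first two MSD
points, ``D = (MSD(2Δt) − MSD(Δt)) / (2 · dim · Δt)`` — a linear function
of the MSD values, so the mean of per-trajectory estimates equals the
estimate from the average MSD curve exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, EstimationError, ParameterError
from .io import Trajectory

#: column order of the per-trajectory metrics table
TRAJECTORY_SUMMARY_FIELDS = [
    "trajectory_id",
    "video_id",
    "condition",
    "n_points",
    "n_steps",
    "avg_step_nm",
    "max_rstep_nm",
    "rstep_var_nm2",
    "extent_nm",
    "accumulated_distance_nm",
    "d_nm2_per_s",
    "d_x_nm2_per_s",
    "d_y_nm2_per_s",
]


@dataclass
class StepSeries:
    """Single-frame displacements of one trajectory with turning angles.

    ``angles`` holds the signed angle (degrees, in (−180, 180]) from each
    step vector to the next; there is one angle per successive step pair.
    ``step_times`` is the time of the frame each step starts from.
    """

    trajectory_id: str
    dx: np.ndarray  # nm
    dy: np.ndarray  # nm
    r_step: np.ndarray  # nm
    step_times: np.ndarray  # s
    angles: np.ndarray  # degrees in (-180, 180]

    def __len__(self) -> int:
        return len(self.r_step)


@dataclass
class MSDCurve:
    """Time-averaged MSD per lag. MSD(0) = 0 by definition and is not stored."""

    lags: np.ndarray  # s, multiples of the frame interval, starting at 1 interval
    msd: np.ndarray  # nm²
    n_pairs: np.ndarray  # displacement pairs (single curve) or trajectories (average)
    se: np.ndarray  # nm²; nan where undefined

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(self.msd < 0):
            raise DataError("MSD values must be non-negative")


@dataclass
class DiffusionEstimate:
    """Diffusion constant in nm²/s; may be negative for noisy single tracks."""

    value: float
    se: float | None  # None for a single trajectory
    dimensionality: int
    method: str
    n: int = 1
    note: str = ""


def compute_steps(traj: Trajectory) -> StepSeries:
    """Per-frame displacements, R-steps, and signed turning angles."""
    gaps = np.diff(traj.frames)
    if len(gaps) and np.any(gaps != gaps[0]):
        raise DataError(
            f"trajectory {traj.trajectory_id}: non-uniform frame spacing (gaps must be handled upstream)"
        )
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    r = np.hypot(dx, dy)
    if len(dx) >= 2:
        cross = dx[:-1] * dy[1:] - dy[:-1] * dx[1:]
        dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
        angles = np.degrees(np.arctan2(cross, dot))
        angles[angles <= -180.0] = 180.0  # convention: (-180, 180]
    else:
        angles = np.empty(0)
    return StepSeries(
        trajectory_id=traj.trajectory_id,
        dx=dx,
        dy=dy,
        r_step=r,
        step_times=traj.times[:-1],
        angles=angles,
    )


def _coords(traj: Trajectory, coords: str) -> np.ndarray:
    if coords == "xy":
        return traj.positions
    if coords == "x":
        return traj.x[:, None]
    if coords == "y":
        return traj.y[:, None]
    raise ParameterError("coords must be 'xy', 'x' or 'y'")


def compute_msd(traj: Trajectory, max_lag: float | None = None, coords: str = "xy") -> MSDCurve:
    """Time-averaged MSD over all overlapping pairs, up to ``max_lag`` seconds.

    ``coords`` selects the 2D displacement ('xy', default) or a single axis
    for per-axis diffusion diagnostics.
    """
    dt = float(np.diff(traj.times)[0]) if len(traj) > 1 else 0.0
    if max_lag is not None and max_lag < dt:
        raise ParameterError("max_lag must be at least one frame interval")
    p = _coords(traj, coords)
    n = len(p)
    k_max = n - 1 if max_lag is None else min(n - 1, int(np.floor(max_lag / dt)))
    lags = np.arange(1, k_max + 1) * dt
    msd = np.empty(k_max)
    n_pairs = np.empty(k_max, dtype=np.int64)
    se = np.empty(k_max)
    for k in range(1, k_max + 1):
        sq = np.sum((p[k:] - p[:-k]) ** 2, axis=1)
        msd[k - 1] = sq.mean()
        n_pairs[k - 1] = len(sq)
        se[k - 1] = sq.std(ddof=1) / np.sqrt(len(sq)) if len(sq) > 1 else np.nan
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs, se=se)


def average_msd(curves) -> MSDCurve:
    """Unweighted per-lag mean across trajectories contributing that lag.

    ``n_pairs`` of the result counts contributing trajectories per lag; the
    standard error is across trajectories (nan where only one contributes).
    Curves must share the lag grid (same frame interval).
    """
    curves = list(curves)
    if not curves:
        raise ParameterError("average_msd needs at least one curve")
    base = min((c.lags[0] for c in curves if len(c.lags)), default=None)
    if base is None:
        raise ParameterError("average_msd needs curves with at least one lag")
    for c in curves:
        if len(c.lags) and not np.allclose(c.lags, base * np.arange(1, len(c.lags) + 1)):
            raise ParameterError("curves do not share a common lag grid")
    k_max = max(len(c.lags) for c in curves)
    lags = base * np.arange(1, k_max + 1)
    msd = np.empty(k_max)
    n_traj = np.empty(k_max, dtype=np.int64)
    se = np.empty(k_max)
    for k in range(k_max):
        vals = np.array([c.msd[k] for c in curves if len(c.msd) > k])
        msd[k] = vals.mean()
        n_traj[k] = len(vals)
        se[k] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_traj, se=se)


def estimate_diffusion(curve: MSDCurve, dimensionality: int = 2) -> DiffusionEstimate:
    """Two-point diffusion estimate from the first two MSD points.

    ``D = (MSD(2Δt) − MSD(Δt)) / (2 · dim · Δt)``. The two-point slope is
    insensitive to a constant MSD offset, so static localization noise
    cancels. Negative values can occur on noisy single tracks and are
    preserved, not clipped.
    """
    if dimensionality not in (1, 2):
        raise ParameterError("dimensionality must be 1 or 2")
    if len(curve.lags) < 2:
        raise EstimationError("MSD curve lacks the first two lags")
    dt = float(curve.lags[0])
    d = (curve.msd[1] - curve.msd[0]) / (2.0 * dimensionality * dt)
    return DiffusionEstimate(
        value=float(d), se=None, dimensionality=dimensionality, method="two-point", n=1
    )


def diffusion_per_trajectory(trajectories, coords: str = "xy") -> np.ndarray:
    """Two-point D for each trajectory (nm²/s); dim follows ``coords``."""
    dim = 2 if coords == "xy" else 1
    return np.array(
        [
            estimate_diffusion(compute_msd(t, coords=coords), dimensionality=dim).value
            for t in trajectories
        ]
    )


def mean_diffusion(trajectories, coords: str = "xy") -> DiffusionEstimate:
    """Mean ± SE of per-trajectory two-point D across trajectories."""
    values = diffusion_per_trajectory(trajectories, coords=coords)
    if len(values) == 0:
        raise EstimationError("no trajectories")
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else None
    return DiffusionEstimate(
        value=float(values.mean()),
        se=se,
        dimensionality=2 if coords == "xy" else 1,
        method="two-point, mean across trajectories",
        n=len(values),
    )


def axis_diffusion(trajectories, axis: str) -> DiffusionEstimate:
    """Mean ± SE of per-trajectory 1D two-point D along one axis."""
    if axis not in ("x", "y"):
        raise ParameterError("axis must be 'x' or 'y'")
    return mean_diffusion(trajectories, coords=axis)


def trajectory_summary(traj: Trajectory) -> dict:
    """Per-trajectory mobility record (Table-1-style inputs).

    Returns average/maximum R-step (nm), R-step variance (nm²), spatial
    extent (nm), accumulated distance (nm, sum of R-steps), and the 2D and
    per-axis two-point diffusion constants.
    """
    from .preprocess import spatial_extent  # local import avoids a cycle

    steps = compute_steps(traj)
    r = steps.r_step
    d2 = estimate_diffusion(compute_msd(traj)).value if len(traj) >= 3 else np.nan
    dx = estimate_diffusion(compute_msd(traj, coords="x"), 1).value if len(traj) >= 3 else np.nan
    dy = estimate_diffusion(compute_msd(traj, coords="y"), 1).value if len(traj) >= 3 else np.nan
    return {
        "trajectory_id": traj.trajectory_id,
        "video_id": traj.video_id,
        "condition": traj.condition,
        "n_points": len(traj),
        "n_steps": len(r),
        "avg_step_nm": float(r.mean()),
        "max_rstep_nm": float(r.max()),
        "rstep_var_nm2": float(r.var(ddof=1)) if len(r) > 1 else 0.0,
        "extent_nm": spatial_extent(traj),
        "accumulated_distance_nm": float(r.sum()),
        "d_nm2_per_s": d2,
        "d_x_nm2_per_s": dx,
        "d_y_nm2_per_s": dy,
    }


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = values[np.isfinite(values)]
    mean = float(values.mean()) if len(values) else np.nan
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else np.nan
    return mean, se


def condition_summary(trajectories, condition: str = "") -> dict:
    """Per-condition summary across accepted trajectories.

    Mean ± SE of per-trajectory diffusion constant, average step size,
    maximum R-step and R-step variance; SE is the across-trajectory
    standard deviation over √n and is nan for n = 1.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ParameterError("condition_summary needs at least one trajectory")
    records = [trajectory_summary(t) for t in trajectories]

    def col(name):
        return np.array([r[name] for r in records], dtype=float)

    d_mean, d_se = _mean_se(col("d_nm2_per_s"))
    step_mean, step_se = _mean_se(col("avg_step_nm"))
    max_mean, max_se = _mean_se(col("max_rstep_nm"))
    var_mean, var_se = _mean_se(col("rstep_var_nm2"))
    return {
        "condition": condition or trajectories[0].condition,
        "n_trajectories": len(trajectories),
        "n_steps": int(sum(r["n_steps"] for r in records)),
        "d_mean_nm2_per_s": d_mean,
        "d_se_nm2_per_s": d_se,
        "avg_step_mean_nm": step_mean,
        "avg_step_se_nm": step_se,
        "max_rstep_mean_nm": max_mean,
        "max_rstep_se_nm": max_se,
        "rstep_var_mean_nm2": var_mean,
        "rstep_var_se_nm2": var_se,
    }
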