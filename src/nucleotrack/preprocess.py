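"""Frame decimation, per-video drift correction, and trajectory QC.

The raster AFM tip scans top-to-bottom then bottom-to-top, so successive
raw frames sample the same surface region at unequal phases; analysis
therefore keeps every other frame, doubling the frame interval to the
effective 2 s. Stage drift — slow coherent motion shared by all particles
of a video — is estimated from the mean inter-frame displacement across
particles and subtracted before any per-particle statistic. QC then
partitions trajectories into accepted, stuck, and rejected sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CoverageError, EstimationError, ParameterError
from .io import Trajectory, VideoDataset

STATUS_ACCEPTED = "accepted"
STATUS_STUCK = "stuck"
STATUS_TOO_SHORT = "too_short"
STATUS_TRUNCATED = "too_long_truncated"
STATUS_STEP_EXCEEDED = "step_exceeded"

#: statuses whose trajectories enter the mobility analysis
ACCEPTED_STATUSES = (STATUS_ACCEPTED, STATUS_TRUNCATED)


@dataclass
class DriftModel:
    """Cumulative per-frame drift of one video, anchored at (0, 0)."""

    video_id: str
    frames: np.ndarray  # observed frame indices, sorted
    dx: np.ndarray  # nm, cumulative
    dy: np.ndarray  # nm, cumulative

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if len(self.frames) and (self.dx[0] != 0.0 or self.dy[0] != 0.0):
            raise ParameterError("cumulative drift must be 0 at the first observed frame")

    def at(self, frames: np.ndarray) -> np.ndarray:
        """(n, 2) cumulative drift for the requested frame indices."""
        idx = np.searchsorted(self.frames, frames)
        ok = (idx < len(self.frames)) & (self.frames[np.minimum(idx, len(self.frames) - 1)] == frames)
        if not np.all(ok):
            missing = np.asarray(frames)[~ok]
            raise CoverageError(f"no drift entry for frame(s) {missing[:5].tolist()}")
        return np.column_stack([self.dx[idx], self.dy[idx]])


@dataclass
class QCRules:
    """Thresholds of the trajectory selection rules (all configurable)."""

    min_points: int = 10
    max_points: int = 60
    max_step_nm: float = 24.0
    stuck_avg_rstep_nm: float = 1.0
    stuck_extent_nm: float = 8.0
    stuck_logic: str = "and"  # how the two stuck conditions combine

    def __post_init__(self) -> None:
        if self.min_points < 2 or self.max_points < self.min_points:
            raise ParameterError("require 2 <= min_points <= max_points")
        if min(self.max_step_nm, self.stuck_avg_rstep_nm, self.stuck_extent_nm) <= 0:
            raise ParameterError("thresholds must be positive")
        if self.stuck_logic not in ("and", "or"):
            raise ParameterError("stuck_logic must be 'and' or 'or'")


@dataclass
class QCDecision:
    """Outcome of the QC rules for one trajectory, with the metrics used."""

    trajectory_id: str
    status: str
    n_points: int
    avg_rstep_nm: float
    max_rstep_nm: float
    extent_nm: float


@dataclass
class QCResult:
    """Partition of a video's trajectories: every input lands in exactly one set."""

    accepted: list
    stuck: list
    rejected: list
    decisions: list


def decimate_frames(video: VideoDataset, keep_parity: str = "even") -> VideoDataset:
    """Keep every other frame of a video acquired at the full scan rate.

    Retains frames of the chosen parity, renumbers them 0, 1, 2, ... and
    doubles the frame interval; trajectories reduced below 2 frames are
    dropped. Applying this to an already-decimated video halves the frames
    again — decimation is not idempotent and must be run exactly once.
    """
    if keep_parity not in ("even", "odd"):
        raise ParameterError("keep_parity must be 'even' or 'odd'")
    parity = 0 if keep_parity == "even" else 1
    new_dt = 2.0 * video.frame_interval
    kept = []
    for t in video.trajectories:
        mask = (t.frames % 2) == parity
        if mask.sum() < 2:
            continue
        frames = np.arange(int(mask.sum()), dtype=np.int64)
        kept.append(
            Trajectory(
                trajectory_id=t.trajectory_id,
                video_id=t.video_id,
                condition=t.condition,
                frames=frames,
                times=frames * new_dt,
                x=t.x[mask],
                y=t.y[mask],
            )
        )
    return VideoDataset(
        video_id=video.video_id,
        condition=video.condition,
        frame_interval=new_dt,
        trajectories=kept,
    )


def estimate_drift(video: VideoDataset) -> DriftModel:
    """Estimate per-video drift from the mean inter-frame displacement.

    For each consecutive pair of observed frames the drift increment is the
    mean displacement over all particles present in both frames (intrinsic
    Brownian motion averages toward zero across particles); frame pairs
    sharing no particle get a zero increment. The cumulative sum is anchored
    at zero on the first observed frame.
    """
    frames = video.all_frames
    if len(frames) < 2:
        raise EstimationError(f"video {video.video_id}: no frame pairs to estimate drift from")
    frame_index = {int(f): i for i, f in enumerate(frames)}
    per_frame = [dict() for _ in frames]
    for t in video.trajectories:
        for k, f in enumerate(t.frames):
            per_frame[frame_index[int(f)]][t.trajectory_id] = (t.x[k], t.y[k])
    increments = np.zeros((len(frames) - 1, 2))
    any_pair = False
    for i in range(len(frames) - 1):
        a, b = per_frame[i], per_frame[i + 1]
        shared = a.keys() & b.keys()
        if shared:
            any_pair = True
            disp = np.array([[b[s][0] - a[s][0], b[s][1] - a[s][1]] for s in sorted(shared)])
            increments[i] = disp.mean(axis=0)
    if not any_pair:
        raise EstimationError(f"video {video.video_id}: no particle observed in two consecutive frames")
    cum = np.vstack([np.zeros(2), np.cumsum(increments, axis=0)])
    return DriftModel(video_id=video.video_id, frames=frames, dx=cum[:, 0], dy=cum[:, 1])


def apply_drift_correction(video: VideoDataset, drift: DriftModel) -> VideoDataset:
    """Subtract cumulative drift from every coordinate of the video.

    Applying the same model twice shifts coordinates twice; the correction
    is deliberately not idempotent.
    """
    corrected = []
    for t in video.trajectories:
        d = drift.at(t.frames)
        corrected.append(t.with_coords(t.x - d[:, 0], t.y - d[:, 1]))
    return VideoDataset(
        video_id=video.video_id,
        condition=video.condition,
        frame_interval=video.frame_interval,
        trajectories=corrected,
    )


def _rsteps(t: Trajectory) -> np.ndarray:
    return np.hypot(np.diff(t.x), np.diff(t.y))


def spatial_extent(t: Trajectory) -> float:
    """Maximum pairwise distance between positions within the trajectory (nm)."""
    p = t.positions
    d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def qc_filter(video: VideoDataset, rules: QCRules | None = None) -> QCResult:
    """Partition a decimated, drift-corrected video by the selection rules.

    Order of application per trajectory: (a) fewer than ``min_points``
    points → too_short; (b) more than ``max_points`` points → truncated to
    the first ``max_points`` and retained; (c) any single planar step above
    ``max_step_nm`` → step_exceeded (a tracking error: the linker likely
    jumped to a different particle); (d) average R-step below
    ``stuck_avg_rstep_nm`` combined (AND by default) with spatial extent
    below ``stuck_extent_nm`` → stuck, kept separately as the
    surface-adhesion control population; otherwise accepted.
    """
    rules = rules or QCRules()
    accepted, stuck, rejected, decisions = [], [], [], []
    for t in video.trajectories:
        n_in = len(t)
        truncated = False
        if n_in > rules.max_points:
            t = t.slice(slice(0, rules.max_points))
            truncated = True
        r = _rsteps(t)
        avg_r, max_r = float(r.mean()), float(r.max())
        extent = spatial_extent(t)
        if n_in < rules.min_points:
            status = STATUS_TOO_SHORT
        elif max_r > rules.max_step_nm:
            status = STATUS_STEP_EXCEEDED
        else:
            lo_step = avg_r < rules.stuck_avg_rstep_nm
            lo_extent = extent < rules.stuck_extent_nm
            is_stuck = (lo_step and lo_extent) if rules.stuck_logic == "and" else (lo_step or lo_extent)
            if is_stuck:
                status = STATUS_STUCK
            elif truncated:
                status = STATUS_TRUNCATED
            else:
                status = STATUS_ACCEPTED
        decisions.append(
            QCDecision(
                trajectory_id=t.trajectory_id,
                status=status,
                n_points=len(t),
                avg_rstep_nm=avg_r,
                max_rstep_nm=max_r,
                extent_nm=extent,
            )
        )
        if status in ACCEPTED_STATUSES:
            accepted.append(t)
        elif status == STATUS_STUCK:
            stuck.append(t)
        else:
            rejected.append(t)
    return QCResult(accepted=accepted, stuck=stuck, rejected=rejected, decisions=decisions)
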