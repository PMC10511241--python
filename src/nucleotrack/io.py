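"""Reading and writing per-frame particle-coordinate tables.

The on-disk format is a flat CSV with one row per (trajectory, frame):

    video_id,condition,trajectory_id,frame,time_s,x_nm,y_nm

Coordinates are stored in nanometers. Frame indices are 0-based integers and
times are derived as ``frame * frame_interval`` when no time column is
present. Input files with other column names or coordinate units are
absorbed through ``column_map`` and ``unit_factor``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, ParameterError

#: canonical CSV header written by :func:`write_trajectories`
CSV_COLUMNS = ["video_id", "condition", "trajectory_id", "frame", "time_s", "x_nm", "y_nm"]

#: default mapping from canonical roles to column names in the file
DEFAULT_COLUMN_MAP = {
    "video": "video_id",
    "condition": "condition",
    "trajectory": "trajectory_id",
    "frame": "frame",
    "time": "time_s",
    "x": "x_nm",
    "y": "y_nm",
}

REQUIRED_ROLES = ("video", "trajectory", "frame", "x", "y")


@dataclass
class Trajectory:
    """One tracked nucleosome: ordered frames with time (s) and position (nm)."""

    trajectory_id: str
    video_id: str
    condition: str
    frames: np.ndarray  # int, strictly increasing
    times: np.ndarray  # s
    x: np.ndarray  # nm
    y: np.ndarray  # nm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frames)
        if not (len(self.times) == len(self.x) == len(self.y) == n):
            raise DataError(f"trajectory {self.trajectory_id}: ragged arrays")
        if n < 2:
            raise DataError(f"trajectory {self.trajectory_id}: fewer than 2 frames")
        if np.any(np.diff(self.frames) <= 0):
            raise DataError(f"trajectory {self.trajectory_id}: frames not strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DataError(f"trajectory {self.trajectory_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of xy positions in nm."""
        return np.column_stack([self.x, self.y])

    def slice(self, idx: slice) -> "Trajectory":
        return Trajectory(
            self.trajectory_id,
            self.video_id,
            self.condition,
            self.frames[idx],
            self.times[idx],
            self.x[idx],
            self.y[idx],
        )

    def with_coords(self, x: np.ndarray, y: np.ndarray) -> "Trajectory":
        return Trajectory(
            self.trajectory_id, self.video_id, self.condition, self.frames, self.times, x, y
        )


@dataclass
class VideoDataset:
    """All trajectories of one video/condition sharing a frame interval."""

    video_id: str
    condition: str
    frame_interval: float  # s
    trajectories: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        for t in self.trajectories:
            if t.video_id != self.video_id:
                raise DataError(
                    f"trajectory {t.trajectory_id} has video_id {t.video_id!r}, "
                    f"expected {self.video_id!r}"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def all_frames(self) -> np.ndarray:
        """Sorted union of frame indices observed in the video."""
        if not self.trajectories:
            return np.array([], dtype=np.int64)
        return np.unique(np.concatenate([t.frames for t in self.trajectories]))


def read_trajectories(
    path,
    column_map: dict | None = None,
    frame_interval: float = 2.0,
    unit_factor: float = 1.0,
) -> list[VideoDataset]:
    """Read a coordinate table into per-video datasets.

    Parameters
    ----------
    path
        CSV file with one row per (trajectory, frame).
    column_map
        Mapping from canonical roles (``video``, ``trajectory``, ``frame``,
        ``x``, ``y``, optionally ``time`` and ``condition``) to the column
        names actually present; defaults to the canonical header.
    frame_interval
        Seconds per frame, used to derive times when no time column exists.
    unit_factor
        Nanometers per coordinate unit in the file (1.0 if already nm).

    Returns
    -------
    list of VideoDataset, grouped by video id, rows sorted by
    (trajectory, frame). Duplicate (video, trajectory, frame) rows are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if frame_interval <= 0:
        raise ParameterError("frame_interval must be > 0")
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    df = pd.read_csv(path, dtype=str)
    for role in REQUIRED_ROLES:
        if cmap[role] not in df.columns:
            raise FormatError(f"missing column: {cmap[role]}")

    def numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"unparseable numeric cell in column {col!r}, data row {row}")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise DataError(f"missing value in column {col!r}, data row {row}")
        return vals.to_numpy(dtype=float)

    out = pd.DataFrame(
        {
            "video": df[cmap["video"]].astype(str),
            "trajectory": df[cmap["trajectory"]].astype(str),
            "frame": numeric(cmap["frame"]).astype(np.int64),
            "x": numeric(cmap["x"]) * unit_factor,
            "y": numeric(cmap["y"]) * unit_factor,
        }
    )
    if cmap.get("condition") in df.columns:
        out["condition"] = df[cmap["condition"]].astype(str)
    else:
        out["condition"] = ""
    if cmap.get("time") in df.columns:
        out["time"] = numeric(cmap["time"])
    else:
        out["time"] = out["frame"] * frame_interval

    dup = out.duplicated(subset=["video", "trajectory", "frame"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataError(f"duplicate (trajectory, frame) at data row {row}")
    out = out.sort_values(["video", "trajectory", "frame"], kind="mergesort")

    datasets = []
    for vid, vgrp in out.groupby("video", sort=True):
        trajs = []
        for tid, tgrp in vgrp.groupby("trajectory", sort=True):
            trajs.append(
                Trajectory(
                    trajectory_id=str(tid),
                    video_id=str(vid),
                    condition=str(tgrp["condition"].iloc[0]),
                    frames=tgrp["frame"].to_numpy(),
                    times=tgrp["time"].to_numpy(),
                    x=tgrp["x"].to_numpy(),
                    y=tgrp["y"].to_numpy(),
                )
            )
        condition = trajs[0].condition if trajs else ""
        datasets.append(
            VideoDataset(
                video_id=str(vid),
                condition=condition,
                frame_interval=frame_interval,
                trajectories=trajs,
            )
        )
    return datasets


def write_trajectories(datasets, path) -> Path:
    """Write datasets to one canonical CSV; stable (video, trajectory, frame) order."""
    datasets = list(datasets)
    if not datasets or all(len(d) == 0 for d in datasets):
        raise ParameterError("no trajectories to write")
    rows = []
    for ds in sorted(datasets, key=lambda d: d.video_id):
        for t in sorted(ds.trajectories, key=lambda t: t.trajectory_id):
            rows.append(
                pd.DataFrame(
                    {
                        "video_id": t.video_id,
                        "condition": t.condition,
                        "trajectory_id": t.trajectory_id,
                        "frame": t.frames,
                        "time_s": t.times,
                        "x_nm": t.x,
                        "y_nm": t.y,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)[CSV_COLUMNS]
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6f")
    return path


def read_manifest(path) -> dict:
    """Read a condition manifest (YAML or JSON).

    A manifest lists input files with their condition label, coordinate unit
    factor (nm per unit), frame interval, and whether drift correction was
    already applied upstream::

        frame_interval: 2.0
        inputs:
          - file: low_salt.csv
            condition: low salt
            unit_factor: 1.0
            drift_corrected: false
    """
    path = Path(path)
    text = path.read_text()
    manifest = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(manifest, dict) or "inputs" not in manifest:
        raise FormatError("manifest must be a mapping with an 'inputs' list")
    manifest.setdefault("frame_interval", 2.0)
    for entry in manifest["inputs"]:
        if "file" not in entry:
            raise FormatError("every manifest input needs a 'file' key")
        entry.setdefault("condition", "")
        entry.setdefault("unit_factor", 1.0)
        entry.setdefault("drift_corrected", False)
    return manifest


def load_manifest(path) -> list[tuple[VideoDataset, dict]]:
    """Load every input of a manifest; returns (dataset, manifest entry) pairs."""
    path = Path(path)
    manifest = read_manifest(path)
    pairs = []
    for entry in manifest["inputs"]:
        fpath = Path(entry["file"])
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        datasets = read_trajectories(
            fpath,
            column_map=entry.get("column_map"),
            frame_interval=float(entry.get("frame_interval", manifest["frame_interval"])),
            unit_factor=float(entry["unit_factor"]),
        )
        for ds in datasets:
            if entry["condition"]:
                ds.condition = entry["condition"]
                for t in ds.trajectories:
                    t.condition = entry["condition"]
            pairs.append((ds, entry))
    return pairs
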