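"""Shared containers and on-disk formats.

A :class:`Trajectory` is the time-ordered record of one localized particle:
frame index, time, x/y position in nanometres, and spot intensity.  The
trajectory CSV schema (``molecule_id, frame, t_s, x_nm, y_nm, intensity``,
one row per localized frame) is the interchange format between the
simulator, the localizer and the segmentation stage, so externally supplied
tracking tables can enter the pipeline at the same point.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = ["molecule_id", "frame", "t_s", "x_nm", "y_nm", "intensity"]


@dataclass
class Trajectory:
    """Time-ordered localized positions and intensity for one particle.

    Positions are in nanometres in the lab frame (origin at the image
    corner, x right / y down); frames are 0-based and strictly increasing.
    """

    molecule_id: int
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = len(self.frames)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.intensity) == n):
            raise ValueError("trajectory arrays must have equal length")
        if n > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def landing_time(self) -> float:
        return float(self.t[0])

    @property
    def bound_duration(self) -> float:
        """Observed bound time, counting each frame as one frame interval."""
        if len(self) == 0:
            return 0.0
        if len(self) == 1:
            return 0.0
        dt = float(np.median(np.diff(self.t) / np.diff(self.frames)))
        return float(self.t[-1] - self.t[0] + dt)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": self.molecule_id,
                "frame": self.frames,
                "t_s": self.t,
                "x_nm": self.x,
                "y_nm": self.y,
                "intensity": self.intensity,
            }
        )


def trajectories_to_dataframe(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    frames = [t.to_dataframe() for t in trajectories]
    if not frames:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_trajectories(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    trajectories_to_dataframe(trajectories).to_csv(path, index=False, float_format="%.6g")


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    out = []
    for mol_id, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                molecule_id=int(mol_id),
                frames=grp["frame"].to_numpy(),
                t=grp["t_s"].to_numpy(),
                x=grp["x_nm"].to_numpy(),
                y=grp["y_nm"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return out


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):  # noqa: D102
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    """Write JSON deterministically (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(obj, cls=_NumpyJSONEncoder, sort_keys=True, indent=1) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
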