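"""Trajectory container and localization-table I/O.

Internal length unit for single-particle tracking is the micrometre (µm);
on-disk CSV tables use nanometres (columns ``x_nm``/``y_nm``) so that SPT and
STORM tables share one dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NM_PER_UM = 1000.0


def um_to_nm(x):
    """Explicit µm → nm conversion."""
    return np.asarray(x, dtype=float) * NM_PER_UM


def nm_to_um(x):
    """Explicit nm → µm conversion."""
    return np.asarray(x, dtype=float) / NM_PER_UM


@dataclass
class Trajectory:
    """Time-ordered 2D localizations of one particle.

    Parameters
    ----------
    particle_id : int
        Identifier carried through linking and metric tables.
    frames : ndarray of int
        Strictly increasing acquisition frame indices. Missing frames
        (blinking gaps) are simply absent.
    xy : ndarray, shape (n, 2)
        Positions in µm.
    frame_interval : float
        Acquisition interval τ in seconds.
    """

    particle_id: int
    frames: np.ndarray
    xy: np.ndarray
    frame_interval: float
    intensity: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise ValueError("frames must be 1D and xy of shape (n_frames, 2)")
        if self.frames.size < 2:
            raise ValueError("a trajectory needs at least 2 localizations")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.frames.size

    @property
    def n_span(self) -> int:
        """Number of frames spanned, including gaps."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def gap_frames(self) -> np.ndarray:
        """Frame indices inside the span with no localization."""
        full = np.arange(self.frames[0], self.frames[-1] + 1)
        return np.setdiff1d(full, self.frames)

    @property
    def duration(self) -> float:
        """Observed duration in seconds (span × τ)."""
        return self.n_span * self.frame_interval


def trajectories_to_table(trajs: list[Trajectory]) -> pd.DataFrame:
    """Long-format table (track_id, frame, x_nm, y_nm) from trajectories."""
    parts = []
    for t in trajs:
        parts.append(
            pd.DataFrame(
                {
                    "track_id": t.particle_id,
                    "frame": t.frames,
                    "x_nm": um_to_nm(t.xy[:, 0]),
                    "y_nm": um_to_nm(t.xy[:, 1]),
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=["track_id", "frame", "x_nm", "y_nm"])
    return pd.concat(parts, ignore_index=True)


def table_to_trajectories(table: pd.DataFrame, frame_interval: float) -> list[Trajectory]:
    """Rebuild Trajectory objects from a long-format track table (nm columns)."""
    out = []
    for pid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                particle_id=int(pid),
                frames=grp["frame"].to_numpy(),
                xy=np.column_stack(
                    [nm_to_um(grp["x_nm"].to_numpy()), nm_to_um(grp["y_nm"].to_numpy())]
                ),
                frame_interval=frame_interval,
            )
        )
    return out


def write_trajectories_csv(trajs: list[Trajectory], path) -> None:
    trajectories_to_table(trajs).to_csv(path, index=False)


def read_trajectories_csv(path, frame_interval: float) -> list[Trajectory]:
    return table_to_trajectories(pd.read_csv(path), frame_interval)
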