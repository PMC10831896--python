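"""Trajectory container and plain-text track-table I/O.

A :class:`Trajectory` is the unit of motion analysis: a time-ordered list of
particle positions (in micrometers) with their frame indices and the frame
interval ``dt``. Trajectories are produced either by the synthetic generator
(with ground truth attached) or by the nearest-neighbor linker.

Track tables are CSV files with the fixed column order
``track_id, frame, x_um, y_um, channel`` and fixed 6-decimal formatting so
that re-running a pipeline with the same seed reproduces byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "channel"]
FLOAT_FORMAT = "%.6f"


@dataclass
class Trajectory:
    """Time-ordered particle positions.

    Parameters
    ----------
    id : str or int
        Identifier, unique within one movie/scene.
    frames : ndarray of int
        Strictly increasing frame indices (0-based).
    positions : ndarray, shape (n, 2)
        x, y coordinates in micrometers.
    dt : float
        Frame interval in seconds.
    channel : str
        Detection channel the track belongs to.
    meta : dict
        Free-form annotations (ground-truth motion mode, linker settings...).
    """

    id: object
    frames: np.ndarray
    positions: np.ndarray
    dt: float
    channel: str = "ch0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions length mismatch")
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite coordinates")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Track duration (n - 1) * dt in seconds."""
        return (len(self) - 1) * self.dt

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    def displacements(self) -> np.ndarray:
        """Euclidean displacement between consecutive points (μm)."""
        return np.hypot(*np.diff(self.positions, axis=0).T[::-1])


def tracks_to_table(tracks: Iterable[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into a tidy track table."""
    rows = []
    for t in tracks:
        rows.append(
            pd.DataFrame(
                {
                    "track_id": t.id,
                    "frame": t.frames,
                    "x_um": t.positions[:, 0],
                    "y_um": t.positions[:, 1],
                    "channel": t.channel,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]


def table_to_tracks(table: pd.DataFrame, dt: float) -> list[Trajectory]:
    """Rebuild :class:`Trajectory` objects from a track table."""
    out = []
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        channel = grp["channel"].iloc[0] if "channel" in grp else "ch0"
        out.append(
            Trajectory(
                id=tid,
                frames=grp["frame"].to_numpy(),
                positions=grp[["x_um", "y_um"]].to_numpy(),
                dt=dt,
                channel=str(channel),
            )
        )
    return out


def write_tracks(path, tracks: Sequence[Trajectory]) -> None:
    tracks_to_table(tracks).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_tracks(path, dt: float) -> list[Trajectory]:
    return table_to_tracks(pd.read_csv(path), dt=dt)
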