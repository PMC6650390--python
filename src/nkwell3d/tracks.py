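"""Track container and CSV I/O.

A :class:`Track` is the time-ordered 3D trajectory of one cell in physical
units (um, min).  Collections of tracks round-trip through a flat CSV table
with columns ``cell_id, cell_type, frame, t_min, x_um, y_um, z_um`` plus the
optional ground-truth columns ``true_mode`` and ``alive``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["cell_id", "cell_type", "frame", "t_min", "x_um", "y_um", "z_um"]


@dataclass
class Track:
    """Time-ordered 3D positions of a single cell.

    Attributes
    ----------
    cell_id : int
        Unique identifier within a track set.
    cell_type : str
        ``"NK"`` or ``"target"``.
    t : ndarray, shape (N,)
        Frame times in minutes, strictly increasing, uniformly spaced.
    pos : ndarray, shape (N, 3)
        Positions (x, y, z) in micrometres.
    frames : ndarray, shape (N,)
        Integer frame indices.
    """

    cell_id: int
    cell_type: str
    t: np.ndarray
    pos: np.ndarray
    frames: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.t.ndim != 1 or self.pos.shape != (self.t.size, 3):
            raise ValueError("t must be (N,) and pos (N, 3)")
        if self.t.size < 2:
            raise ValueError("a track needs at least 2 time points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.pos))):
            raise ValueError("times and positions must be finite")
        if self.frames is None:
            dt = self.dt
            self.frames = np.round((self.t - self.t[0]) / dt).astype(int)
        else:
            self.frames = np.asarray(self.frames, dtype=int)
            if self.frames.shape != self.t.shape:
                raise ValueError("frames must match t in shape")

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        steps = np.diff(self.t)
        return float(steps[0])

    @property
    def t_tot(self) -> float:
        """Track duration in minutes."""
        return float(self.t[-1] - self.t[0])

    @property
    def r_1(self) -> np.ndarray:
        return self.pos[0]

    @property
    def r_end(self) -> np.ndarray:
        return self.pos[-1]

    @property
    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.pos, axis=0), axis=1)

    @property
    def d_tot(self) -> float:
        """Total path length (sum of consecutive step lengths) in um."""
        return float(self.step_lengths.sum())


def tracks_to_dataframe(
    tracks: Sequence[Track],
    modes: Optional[Dict[int, np.ndarray]] = None,
    alive: Optional[Dict[int, np.ndarray]] = None,
) -> pd.DataFrame:
    """Flatten tracks (plus optional per-frame mode/alive annotation) to a table."""
    rows = []
    for tr in tracks:
        df = pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "cell_type": tr.cell_type,
                "frame": tr.frames,
                "t_min": tr.t,
                "x_um": tr.pos[:, 0],
                "y_um": tr.pos[:, 1],
                "z_um": tr.pos[:, 2],
            }
        )
        if modes is not None:
            df["true_mode"] = modes.get(tr.cell_id, np.full(len(tr), "", dtype=object))
        if alive is not None:
            df["alive"] = alive.get(tr.cell_id, np.ones(len(tr), dtype=bool))
        rows.append(df)
    if not rows:
        cols = list(TRACK_COLUMNS)
        if modes is not None:
            cols.append("true_mode")
        if alive is not None:
            cols.append("alive")
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)


def dataframe_to_tracks(df: pd.DataFrame) -> List[Track]:
    """Rebuild :class:`Track` objects from a flat track table."""
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    out: List[Track] = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("frame")
        if len(g) < 2:
            continue  # singleton detections carry no trajectory information
        out.append(
            Track(
                cell_id=int(cid),
                cell_type=str(g["cell_type"].iloc[0]),
                t=g["t_min"].to_numpy(float),
                pos=g[["x_um", "y_um", "z_um"]].to_numpy(float),
                frames=g["frame"].to_numpy(int),
            )
        )
    return out


def write_tracks_csv(path, tracks: Sequence[Track], modes=None, alive=None) -> None:
    tracks_to_dataframe(tracks, modes=modes, alive=alive).to_csv(path, index=False)


def read_tracks_csv(path) -> List[Track]:
    return dataframe_to_tracks(pd.read_csv(path))


def split_by_type(tracks: Sequence[Track]):
    """Partition a track set into (NK tracks, target tracks)."""
    nk = [t for t in tracks if t.cell_type == "NK"]
    tg = [t for t in tracks if t.cell_type == "target"]
    return nk, tg
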