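"""Trajectory container and delimited-text track tables.

A track table is a plain CSV with header
``track_id,frame,t_s,x_um,y_um[,true_mode][,replicate_id][,group]...``:
one row per frame, frames 0-based, times in seconds, positions in
micrometres. x is the along-neurite axis. Extra columns that are constant
within a track (condition labels such as replicate or genotype) survive
a round trip and are exposed as ``Trajectory.meta``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: spacing tolerance (seconds) below which sampling counts as uniform
UNIFORM_TOL_S = 1e-9

REQUIRED_COLUMNS = ("track_id", "frame", "t_s", "x_um", "y_um")


@dataclass
class Trajectory:
    """One particle's uniformly sampled (t, x, y) time series.

    Positions are micrometres; x is the axial (along-neurite) coordinate.
    ``true_mode`` carries the simulator's ground-truth label when known.
    """

    track_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    true_mode: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.times)
        if not (len(self.x) == len(self.y) == n):
            raise ValueError(f"track {self.track_id}: times/x/y length mismatch")
        if n < 2:
            raise ValueError(f"track {self.track_id}: needs >= 2 frames, got {n}")
        for name, arr in (("times", self.times), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"track {self.track_id}: non-finite {name}")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")
        if np.ptp(dts) > UNIFORM_TOL_S:
            raise ValueError(
                f"track {self.track_id}: non-uniform sampling (dt spread {np.ptp(dts):.3g} s)"
            )

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


class TrackTableError(ValueError):
    """Malformed track-table file."""


def project_principal_axis(traj: Trajectory) -> Trajectory:
    """Rotate a raw-frame track so x lies along its principal axis.

    Real tracking output is in camera coordinates; axial displacement
    measures assume x runs along the neurite. The principal axis of the
    centred (x, y) cloud is the natural axial estimate. Returns a new
    trajectory; the original is untouched.
    """
    pts = np.column_stack([traj.x, traj.y])
    centred = pts - pts.mean(axis=0)
    # leading right singular vector = principal direction
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis, perp = vt[0], vt[1]
    return Trajectory(
        track_id=traj.track_id,
        times=traj.times.copy(),
        x=centred @ axis + pts.mean(axis=0) @ axis,
        y=centred @ perp + pts.mean(axis=0) @ perp,
        true_mode=traj.true_mode,
        meta=dict(traj.meta),
    )


def trajectories_to_dataframe(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    frames = []
    for traj in trajectories:
        df = pd.DataFrame(
            {
                "track_id": traj.track_id,
                "frame": np.arange(traj.n_frames, dtype=int),
                "t_s": traj.times,
                "x_um": traj.x,
                "y_um": traj.y,
            }
        )
        if traj.true_mode is not None:
            df["true_mode"] = traj.true_mode
        for key, val in traj.meta.items():
            df[key] = val
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def write_tracks(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    """Write trajectories to a track-table CSV (full float precision)."""
    trajectories_to_dataframe(trajectories).to_csv(path, index=False)


def _split_uniform_segments(sub: pd.DataFrame, track_id: str) -> list[pd.DataFrame]:
    """Split one track's rows at every sampling gap into uniform segments."""
    t = sub["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        return [sub]
    dts = np.diff(t)
    dt = np.min(dts[dts > 0]) if np.any(dts > 0) else 0.0
    breaks = np.nonzero(np.abs(dts - dt) > UNIFORM_TOL_S)[0]
    if len(breaks) == 0:
        return [sub]
    pieces = np.split(np.arange(len(t)), breaks + 1)
    logger.warning(
        "track %s: non-uniform sampling, split into %d segments", track_id, len(pieces)
    )
    return [sub.iloc[idx] for idx in pieces]


def dataframe_to_trajectories(table: pd.DataFrame) -> list[Trajectory]:
    """Build Trajectory objects from a track table, splitting at gaps.

    Tracks whose sampling is interrupted (missing frames, irregular dt)
    are split at each gap into uniform segments with ids suffixed
    ``_s0``, ``_s1``, ...; segments shorter than 2 frames are dropped
    with a warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrackTableError(f"track table missing columns: {missing}")
    extra_cols = [c for c in table.columns if c not in REQUIRED_COLUMNS and c != "true_mode"]
    out: list[Trajectory] = []
    for track_id, sub in table.groupby("track_id", sort=False):
        sub = sub.sort_values("frame")
        segments = _split_uniform_segments(sub, str(track_id))
        multi = len(segments) > 1
        for i, seg in enumerate(segments):
            seg_id = f"{track_id}_s{i}" if multi else str(track_id)
            if len(seg) < 2:
                logger.warning("dropping 1-frame segment %s", seg_id)
                continue
            true_mode = None
            if "true_mode" in seg.columns:
                val = seg["true_mode"].iloc[0]
                true_mode = None if pd.isna(val) else str(val)
            meta = {c: seg[c].iloc[0] for c in extra_cols}
            out.append(
                Trajectory(
                    track_id=seg_id,
                    times=seg["t_s"].to_numpy(dtype=float),
                    x=seg["x_um"].to_numpy(dtype=float),
                    y=seg["y_um"].to_numpy(dtype=float),
                    true_mode=true_mode,
                    meta=meta,
                )
            )
    return out


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a track-table CSV; malformed rows raise with the line."""
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TrackTableError(f"{path}: empty file without header") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrackTableError(f"{path}: missing columns {missing}")
    for col in ("frame", "t_s", "x_um", "y_um"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna() | table[col].isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise TrackTableError(f"{path}: malformed value in column {col!r} at line {line}")
        table[col] = coerced
    return table


def read_tracks(path: str | Path) -> list[Trajectory]:
    """Read a track-table CSV into trajectories (gap-splitting applied)."""
    return dataframe_to_trajectories(read_track_table(path))
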