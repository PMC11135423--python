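"""Axial displacement features and directionality classification.

Net displacement (ND) is the magnitude of the axial (x) difference
between a track's last and first frames; lateral maximal displacement
(LMD) is the largest axial excursion from the start over all frames, so
ND <= LMD always. A particle is called directed when ND > 5 um,
stationary when ND < 5 um and LMD < 1 um, and oscillatory otherwise
(large excursions without net progress). Boundary values fall to
oscillatory by evaluation order, the published inequalities being strict.
Both features are sign-blind: a 6-um retrograde run is as directed as an
anterograde one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Thresholds
from .tracks import Trajectory

DIRECTIONALITY_CLASSES = ("directed", "stationary", "oscillatory")


@dataclass(frozen=True)
class DisplacementResult:
    nd: float  # micrometres
    lmd: float  # micrometres
    directionality: str


def compute_nd(traj: Trajectory) -> float:
    """|x_last - x_first| in micrometres."""
    if traj.n_frames < 2:
        raise ValueError("trajectory needs >= 2 frames")
    return float(abs(traj.x[-1] - traj.x[0]))


def compute_lmd(traj: Trajectory) -> float:
    """max_t |x(t) - x_first| in micrometres."""
    if traj.n_frames < 2:
        raise ValueError("trajectory needs >= 2 frames")
    return float(np.max(np.abs(traj.x - traj.x[0])))


def classify_directionality(nd: float, lmd: float, thr: Thresholds | None = None) -> str:
    thr = thr or Thresholds()
    if nd > thr.nd_directed_um:
        return "directed"
    if lmd < thr.lmd_stationary_um:
        return "stationary"
    return "oscillatory"


def analyze_displacement(traj: Trajectory, thr: Thresholds | None = None) -> DisplacementResult:
    """ND, LMD and the directionality call for one trajectory."""
    nd = compute_nd(traj)
    lmd = compute_lmd(traj)
    return DisplacementResult(nd=nd, lmd=lmd, directionality=classify_directionality(nd, lmd, thr))
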