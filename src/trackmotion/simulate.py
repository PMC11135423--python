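"""Synthetic single-particle trajectories with known motion type.

Three ground-truth regimes mirror the classes the exponent classifier is
meant to separate:

* ``ballistic`` — constant velocity v along +x (motor-driven transport;
  MSD = v^2 tau^2, alpha = 2);
* ``brownian`` — free 2-D diffusion with coefficient D (MSD = 4 D tau,
  alpha = 1);
* ``confined`` — the same diffusion inside a reflecting circular corral
  of radius R (MSD plateaus near the corral size, alpha -> 0 at lags
  beyond R^2 / D).

Localization error is additive i.i.d. Gaussian noise per coordinate,
applied after the physical path. Each track draws from its own RNG
stream derived from (seed, track_id), so generating tracks in a
different order never changes any individual track.
"""

from __future__ import annotations

import zlib
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AcquisitionConfig, MotionSpec
from .tracks import Trajectory, trajectories_to_dataframe


def _track_rng(acq: AcquisitionConfig, track_id: str) -> np.random.Generator:
    """Deterministic per-track stream keyed by (seed, track_id)."""
    key = zlib.crc32(track_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((acq.rng_seed, key)))


def _sample_times(acq: AcquisitionConfig) -> np.ndarray:
    return np.arange(acq.n_frames, dtype=float) * acq.frame_interval


def _with_noise(
    x: np.ndarray, y: np.ndarray, acq: AcquisitionConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if acq.localization_sigma == 0:
        return x, y
    noise = rng.normal(0.0, acq.localization_sigma, size=(2, len(x)))
    return x + noise[0], y + noise[1]


def _brownian_increments(
    spec: MotionSpec, acq: AcquisitionConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n_steps, 2) Gaussian increments with variance 2 D dt per coordinate."""
    step_sd = np.sqrt(2.0 * spec.diffusion_coefficient * acq.frame_interval)
    return rng.normal(0.0, step_sd, size=(acq.n_frames - 1, 2))


def simulate_ballistic(
    spec: MotionSpec, acq: AcquisitionConfig, track_id: str = "track0"
) -> Trajectory:
    """Constant-velocity run along +x plus localization noise."""
    if spec.mode != "ballistic":
        raise ValueError(f"expected ballistic spec, got {spec.mode!r}")
    rng = _track_rng(acq, track_id)
    t = _sample_times(acq)
    x0, y0 = spec.start_position
    x = x0 + spec.velocity * t
    y = np.full_like(t, y0)
    x, y = _with_noise(x, y, acq, rng)
    return Trajectory(track_id, t, x, y, true_mode="ballistic")


def simulate_brownian(
    spec: MotionSpec, acq: AcquisitionConfig, track_id: str = "track0"
) -> Trajectory:
    """Free 2-D diffusion: per-step variance 2 D dt per coordinate."""
    if spec.mode != "brownian":
        raise ValueError(f"expected brownian spec, got {spec.mode!r}")
    rng = _track_rng(acq, track_id)
    t = _sample_times(acq)
    steps = _brownian_increments(spec, acq, rng)
    pos = np.vstack([np.array(spec.start_position), steps]).cumsum(axis=0)
    x, y = _with_noise(pos[:, 0], pos[:, 1], acq, rng)
    return Trajectory(track_id, t, x, y, true_mode="brownian")


def _reflect_into_disc(pos: np.ndarray, centre: np.ndarray, radius: float) -> np.ndarray:
    """Fold a point radially back inside the disc (repeat for large excursions)."""
    for _ in range(64):
        r = np.hypot(*(pos - centre))
        if r <= radius:
            return pos
        # radial mirror at the boundary: r -> 2R - r, angle unchanged
        pos = centre + (pos - centre) * (2.0 * radius - r) / r
    raise RuntimeError("reflection failed to converge (step >> corral size)")


def simulate_confined(
    spec: MotionSpec, acq: AcquisitionConfig, track_id: str = "track0"
) -> Trajectory:
    """Diffusion inside a reflecting disc centred at the start position.

    The increment stream is identical to :func:`simulate_brownian` with
    the same (seed, track_id); in the large-radius limit the reflection
    never triggers and the two simulators produce the same track.
    """
    if spec.mode != "confined":
        raise ValueError(f"expected confined spec, got {spec.mode!r}")
    if not (spec.corral_radius > 0):
        raise ValueError("corral_radius must be > 0")
    rng = _track_rng(acq, track_id)
    t = _sample_times(acq)
    steps = _brownian_increments(spec, acq, rng)
    centre = np.array(spec.start_position, dtype=float)
    pos = np.empty((acq.n_frames, 2))
    pos[0] = centre
    for i, step in enumerate(steps):
        pos[i + 1] = _reflect_into_disc(pos[i] + step, centre, spec.corral_radius)
    x, y = _with_noise(pos[:, 0], pos[:, 1], acq, rng)
    return Trajectory(track_id, t, x, y, true_mode="confined")


_SIMULATORS = {
    "ballistic": simulate_ballistic,
    "brownian": simulate_brownian,
    "confined": simulate_confined,
}


def simulate_track(spec: MotionSpec, acq: AcquisitionConfig, track_id: str = "track0") -> Trajectory:
    """Dispatch to the simulator matching ``spec.mode``."""
    return _SIMULATORS[spec.mode](spec, acq, track_id)


def simulate_tracks(
    spec: MotionSpec,
    acq: AcquisitionConfig,
    n_tracks: int,
    id_prefix: str = "trk",
    meta: Optional[dict] = None,
) -> list[Trajectory]:
    """Simulate ``n_tracks`` i.i.d. tracks of one motion mode."""
    out = []
    for i in range(n_tracks):
        traj = simulate_track(spec, acq, f"{id_prefix}{i:04d}")
        if meta:
            traj.meta.update(meta)
        out.append(traj)
    return out


def simulate_study(
    acq: Optional[AcquisitionConfig] = None,
    groups: Sequence[str] = ("WT", "NKO"),
    n_replicates: int = 4,
    tracks_per_mode: int = 50,
    specs: Optional[dict[str, MotionSpec]] = None,
) -> pd.DataFrame:
    """Balanced multi-replicate, multi-group synthetic study.

    Emulates the live-imaging design: per group, ``n_replicates``
    independent cultures, each contributing ``tracks_per_mode`` tracks
    of every motion mode, acquired at 0.6 s / 90 s with 0.02 um
    localization noise by default. Returns a long-format track table
    with ``replicate_id``, ``group`` and ``true_mode`` columns.
    """
    acq = acq or AcquisitionConfig()
    if specs is None:
        specs = {
            "ballistic": MotionSpec(mode="ballistic", velocity=0.3),
            "brownian": MotionSpec(mode="brownian", diffusion_coefficient=0.1),
            "confined": MotionSpec(
                mode="confined", diffusion_coefficient=0.1, corral_radius=0.2
            ),
        }
    all_tracks: list[Trajectory] = []
    for group in groups:
        for rep in range(n_replicates):
            rep_id = f"{group}_culture{rep}"
            for mode, spec in specs.items():
                all_tracks.extend(
                    simulate_tracks(
                        spec,
                        acq,
                        tracks_per_mode,
                        id_prefix=f"{rep_id}_{mode}_",
                        meta={"replicate_id": rep_id, "group": group},
                    )
                )
    return trajectories_to_dataframe(all_tracks)
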