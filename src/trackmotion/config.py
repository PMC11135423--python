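"""Acquisition, motion and classification parameters.

The defaults encode the live-imaging protocol the analysis was designed
around (one frame every 0.6 s for 90 s) and the published classification
constants: anomalous-exponent windows (active alpha > 1.5, diffusive
0.9 < alpha < 1.1, confined alpha < 0.5), the displacement cut-offs
(net displacement > 5 um => directed, lateral maximal displacement
< 1 um => stationary), the track-length filter (> 20 frames) and the
MSD lag cap (25 % of the track duration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

MODES = ("ballistic", "brownian", "confined")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling geometry of a time-lapse acquisition.

    Parameters
    ----------
    frame_interval : float
        Time between frames, seconds.
    duration : float
        Total acquisition time, seconds. The number of frames is
        ``floor(duration / frame_interval) + 1`` (frame 0 at t = 0).
    localization_sigma : float
        Standard deviation of the additive Gaussian localization error,
        micrometres per coordinate.
    rng_seed : int
        Base seed; per-track streams are derived from (seed, track_id).
    """

    frame_interval: float = 0.6
    duration: float = 90.0
    localization_sigma: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.frame_interval > 0):
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        if not (self.duration >= self.frame_interval):
            raise ValueError(
                f"duration ({self.duration}) must be >= frame_interval "
                f"({self.frame_interval})"
            )
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration / self.frame_interval)) + 1


@dataclass(frozen=True)
class MotionSpec:
    """Ground-truth motion regime for one simulated particle.

    mode 'ballistic' moves at constant ``velocity`` along +x;
    'brownian' diffuses freely with coefficient ``diffusion_coefficient``;
    'confined' diffuses inside a reflecting disc of ``corral_radius``
    centred at ``start_position``. Fields irrelevant to the mode are
    ignored.
    """

    mode: str = "brownian"
    velocity: float = 0.3
    diffusion_coefficient: float = 0.1
    corral_radius: float = 0.2
    start_position: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if self.mode == "confined" and not (self.corral_radius > 0):
            raise ValueError("confined motion requires corral_radius > 0")


@dataclass(frozen=True)
class Thresholds:
    """Classification constants.

    The alpha windows and displacement cut-offs are strict inequalities;
    values on a boundary are not claimed by any named class (alpha
    boundaries fall to 'ambiguous', displacement boundaries to
    'oscillatory' by evaluation order).
    """

    alpha_active: float = 1.5
    alpha_diff_lo: float = 0.9
    alpha_diff_hi: float = 1.1
    alpha_confined: float = 0.5
    nd_directed_um: float = 5.0
    lmd_stationary_um: float = 1.0
    min_frames_exclusive: int = 20
    max_lag_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (
            self.alpha_confined < self.alpha_diff_lo < self.alpha_diff_hi < self.alpha_active
        ):
            raise ValueError("alpha thresholds must be ordered confined < lo < hi < active")
        if self.nd_directed_um <= 0 or self.lmd_stationary_um <= 0:
            raise ValueError("displacement thresholds must be > 0")
        if not (0 < self.max_lag_fraction <= 1):
            raise ValueError("max_lag_fraction must be in (0, 1]")


def _from_mapping(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "start_position" in mapping:
        mapping = {**mapping, "start_position": tuple(mapping["start_position"])}
    return cls(**mapping)


def load_config(path: str | Path) -> dict:
    """Read a YAML config file with optional ``acquisition``, ``thresholds``
    and ``simulation`` sections; returns a dict with dataclass instances."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {
        "acquisition": _from_mapping(AcquisitionConfig, raw.get("acquisition", {}) or {}),
        "thresholds": _from_mapping(Thresholds, raw.get("thresholds", {}) or {}),
    }
    if "simulation" in raw:
        out["simulation"] = raw["simulation"]
    return out
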