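"""Time-averaged MSD, anomalous-diffusion fit and exponent classification.

For a uniformly sampled track the time-averaged mean squared displacement
at lag tau = k*dt is

    MSD(tau) = < [x(t+tau) - x(t)]^2 + [y(t+tau) - y(t)]^2 >_t,

the average running over every overlapping (t, t+tau) pair. Lags are
capped at a fraction of the track duration (default 25 %) because long
lags average too few pairs to be reliable. The curve is then fitted with
the anomalous-diffusion model

    MSD(tau) = A * tau^alpha + B,

where A carries the motion amplitude, B the residual (static/localization)
offset, and the exponent alpha indicates the motion type: tracks are
called actively driven for alpha > 1.5, diffusive for 0.9 < alpha < 1.1,
confined for alpha < 0.5, and ambiguous otherwise (gap values, exact
boundaries, or failed fits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .config import Thresholds
from .tracks import Trajectory

ALPHA_MAX = 3.0  # upper fit bound; keeps ballistic alpha = 2 interior
MOTION_CLASSES = ("active", "diffusive", "confined", "ambiguous")

#: relative spread below which an MSD curve is treated as flat
_FLAT_RTOL = 1e-12


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD at integer-multiple lags of the frame interval."""

    lags: np.ndarray  # seconds, strictly increasing
    msd: np.ndarray  # micrometres^2
    n_pairs: np.ndarray  # pairs averaged per lag


@dataclass(frozen=True)
class AnomalousFit:
    """Bounded least-squares fit of MSD = A tau^alpha + B."""

    A: float
    alpha: float
    B: float
    residual_norm: float
    converged: bool
    n_lags_used: int


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD over all overlapping pairs.

    Lags run k = 1 .. floor(max_lag_fraction * (N - 1)); at least the
    first lag is always returned.
    """
    if not (0 < max_lag_fraction <= 1):
        raise ValueError("max_lag_fraction must be in (0, 1]")
    n = traj.n_frames
    if n < 2:
        raise ValueError("trajectory needs >= 2 frames")
    k_max = max(1, math.floor(max_lag_fraction * (n - 1)))
    dt = traj.dt
    lags = np.empty(k_max)
    msd = np.empty(k_max)
    n_pairs = np.empty(k_max, dtype=int)
    for k in range(1, k_max + 1):
        dx = traj.x[k:] - traj.x[:-k]
        dy = traj.y[k:] - traj.y[:-k]
        lags[k - 1] = k * dt
        msd[k - 1] = np.mean(dx * dx + dy * dy)
        n_pairs[k - 1] = n - k
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs)


def _anomalous(tau: np.ndarray, A: float, alpha: float, B: float) -> np.ndarray:
    return A * np.power(tau, alpha) + B


def fit_anomalous(curve: MSDCurve) -> AnomalousFit:
    """Fit A tau^alpha + B in linear space, unweighted, with bounds
    A >= 0, 0 <= alpha <= 3, B >= 0.

    Curves with fewer than 3 lags, flat curves (A and alpha jointly
    non-identifiable, e.g. a stationary track) and optimizer failures
    return ``converged=False``; such tracks are later labelled ambiguous.
    """
    lags = np.asarray(curve.lags, dtype=float)
    msd = np.asarray(curve.msd, dtype=float)
    if not np.all(np.isfinite(msd)) or not np.all(np.isfinite(lags)):
        raise ValueError("non-finite values in MSD curve")
    n = len(lags)
    if n < 3:
        return AnomalousFit(np.nan, np.nan, np.nan, np.nan, False, n)
    scale = max(abs(float(np.max(msd))), 1.0)
    if np.ptp(msd) <= _FLAT_RTOL * scale:
        return AnomalousFit(np.nan, np.nan, float(np.mean(msd)), np.nan, False, n)
    a0 = max(float(msd[0] / lags[0]), 1e-12)
    try:
        popt, _ = curve_fit(
            _anomalous,
            lags,
            msd,
            p0=[a0, 1.0, 0.0],
            bounds=([0.0, 0.0, 0.0], [np.inf, ALPHA_MAX, np.inf]),
            method="trf",
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return AnomalousFit(np.nan, np.nan, np.nan, np.nan, False, n)
    resid = msd - _anomalous(lags, *popt)
    if popt[1] >= ALPHA_MAX - 1e-6:
        # exponent pinned at the numerical cap: degenerate A -> 0 runaway on
        # plateau-like curves, super-ballistic and non-identifiable
        return AnomalousFit(
            float(popt[0]), float(popt[1]), float(popt[2]),
            float(np.linalg.norm(resid)), False, n,
        )
    return AnomalousFit(
        A=float(popt[0]),
        alpha=float(popt[1]),
        B=float(popt[2]),
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
        n_lags_used=n,
    )


def classify_alpha(fit: AnomalousFit, thr: Thresholds | None = None) -> str:
    """Map a fitted exponent to its motion class.

    Strict inequalities exactly as published: active (alpha > 1.5),
    diffusive (0.9 < alpha < 1.1), confined (alpha < 0.5). Exponents in
    the gaps, on a boundary, or from failed fits are 'ambiguous'.
    """
    thr = thr or Thresholds()
    if not fit.converged or not np.isfinite(fit.alpha):
        return "ambiguous"
    a = fit.alpha
    if a > thr.alpha_active:
        return "active"
    if thr.alpha_diff_lo < a < thr.alpha_diff_hi:
        return "diffusive"
    if a < thr.alpha_confined:
        return "confined"
    return "ambiguous"


def analyze_msd(traj: Trajectory, thr: Thresholds | None = None) -> tuple[MSDCurve, AnomalousFit, str]:
    """Convenience: MSD -> fit -> class for one trajectory."""
    thr = thr or Thresholds()
    curve = compute_msd(traj, thr.max_lag_fraction)
    fit = fit_anomalous(curve)
    return curve, fit, classify_alpha(fit, thr)
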