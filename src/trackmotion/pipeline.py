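"""End-to-end track classification and replicate-level group comparison.

Tracks shorter than the inclusion threshold (more than 20 frames) are
excluded up front. Every retained track receives one motion class from
its fitted exponent and one directionality class from ND/LMD. Class
fractions are computed per replicate (culture) — never pooling tracks
across cultures — then summarised per group as mean +/- SD, and two
groups are compared per class with Welch's unequal-variance t test on
the per-replicate fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds
from .displacement import DIRECTIONALITY_CLASSES, analyze_displacement
from .msd import MOTION_CLASSES, analyze_msd
from .tracks import Trajectory, dataframe_to_trajectories

logger = logging.getLogger(__name__)

CLASS_FAMILIES = {"motion_class": MOTION_CLASSES, "directionality": DIRECTIONALITY_CLASSES}


@dataclass
class GroupSummary:
    """Per-replicate class fractions, group means/SDs and Welch tests."""

    fractions: pd.DataFrame  # group, replicate_id, family, class, fraction, n_tracks
    group_stats: pd.DataFrame  # group, family, class, mean, sd, n_replicates
    comparisons: Optional[pd.DataFrame] = None  # family, class, t, p [, p_holm]
    log: list[str] = field(default_factory=list)


def filter_tracks(
    tracks: Iterable[Trajectory], thr: Thresholds | None = None
) -> tuple[list[Trajectory], list[str]]:
    """Retain tracks with strictly more than ``min_frames_exclusive`` frames.

    Returns (retained, excluded_ids); exclusions are logged with a count.
    """
    thr = thr or Thresholds()
    retained, excluded = [], []
    for traj in tracks:
        (retained if traj.n_frames > thr.min_frames_exclusive else excluded).append(traj)
    excluded_ids = [t.track_id for t in excluded]
    if excluded_ids:
        logger.info(
            "excluded %d tracks with <= %d frames: %s",
            len(excluded_ids),
            thr.min_frames_exclusive,
            excluded_ids,
        )
    return retained, excluded_ids


def analyze_tracks(tracks: Iterable[Trajectory], thr: Thresholds | None = None) -> pd.DataFrame:
    """Per-track record table: fit parameters, motion class, ND/LMD, label."""
    thr = thr or Thresholds()
    records = []
    for traj in tracks:
        _, fit, motion_class = analyze_msd(traj, thr)
        disp = analyze_displacement(traj, thr)
        records.append(
            {
                "track_id": traj.track_id,
                "replicate_id": traj.meta.get("replicate_id", "replicate0"),
                "group": traj.meta.get("group", "all"),
                "mrna": traj.meta.get("mrna", ""),
                "n_frames": traj.n_frames,
                "A": fit.A,
                "alpha": fit.alpha,
                "B": fit.B,
                "converged": fit.converged,
                "motion_class": motion_class,
                "nd_um": disp.nd,
                "lmd_um": disp.lmd,
                "directionality": disp.directionality,
                "true_mode": traj.true_mode if traj.true_mode is not None else "",
            }
        )
    columns = [
        "track_id", "replicate_id", "group", "mrna", "n_frames",
        "A", "alpha", "B", "converged", "motion_class",
        "nd_um", "lmd_um", "directionality", "true_mode",
    ]
    return pd.DataFrame.from_records(records, columns=columns)


def _replicate_fractions(records: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (group, rep), sub in records.groupby(["group", "replicate_id"], sort=True):
        n = len(sub)
        for family, classes in CLASS_FAMILIES.items():
            counts = sub[family].value_counts()
            for cls in classes:
                rows.append(
                    {
                        "group": group,
                        "replicate_id": rep,
                        "family": family,
                        "class": cls,
                        "fraction": counts.get(cls, 0) / n,
                        "n_tracks": n,
                    }
                )
    return pd.DataFrame(rows)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t with the zero-variance case defined.

    When both samples are constant, equal means give (t, p) = (0, 1) and
    unequal means (inf, 0) by the limiting behaviour of the statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t needs >= 2 observations per group")
    se2 = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
    if se2 == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_groups(
    fractions: pd.DataFrame, group_a: str, group_b: str, holm: bool = False
) -> Optional[pd.DataFrame]:
    """Per-class Welch tests on per-replicate fractions; None if a group
    has fewer than 2 replicates (skipped with a warning)."""
    rows = []
    for family, classes in CLASS_FAMILIES.items():
        for cls in classes:
            sel = (fractions["family"] == family) & (fractions["class"] == cls)
            a = fractions.loc[sel & (fractions["group"] == group_a), "fraction"].to_numpy()
            b = fractions.loc[sel & (fractions["group"] == group_b), "fraction"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                logger.warning(
                    "comparison skipped: group %s has %d and %s has %d replicates",
                    group_a, len(a), group_b, len(b),
                )
                return None
            t, p = welch_t(a, b)
            rows.append({"family": family, "class": cls, "t": t, "p": p})
    out = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        out["p_holm"] = np.nan
        for family in out["family"].unique():
            mask = out["family"] == family
            out.loc[mask, "p_holm"] = multipletests(out.loc[mask, "p"], method="holm")[1]
    return out


def summarize_groups(records: pd.DataFrame, holm: bool = False) -> GroupSummary:
    """Aggregate per-track records into per-replicate fractions, group
    mean +/- SD, and (for exactly two groups) Welch comparisons."""
    if records.empty:
        raise ValueError("no records to summarize")
    fractions = _replicate_fractions(records)
    group_stats = (
        fractions.groupby(["group", "family", "class"], sort=True)["fraction"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n_replicates="size")
        .reset_index()
    )
    groups = sorted(records["group"].unique())
    log: list[str] = []
    comparisons = None
    if len(groups) == 2:
        comparisons = compare_groups(fractions, groups[0], groups[1], holm=holm)
        if comparisons is None:
            log.append("group comparison skipped: < 2 replicates in a group")
    elif len(groups) > 2:
        log.append(f"{len(groups)} groups present; pairwise comparison not performed")
    return GroupSummary(fractions=fractions, group_stats=group_stats, comparisons=comparisons, log=log)


def run_pipeline(
    track_table: pd.DataFrame,
    thr: Thresholds | None = None,
    holm: bool = False,
) -> tuple[pd.DataFrame, GroupSummary]:
    """Full analysis of a long-format track table.

    Splits non-uniform tracks, applies the frame filter, classifies every
    retained track by exponent and by displacement, and aggregates per
    replicate and group. Deterministic given the input table.
    """
    thr = thr or Thresholds()
    tracks = dataframe_to_trajectories(track_table)
    retained, excluded = filter_tracks(tracks, thr)
    if not retained:
        raise ValueError("no tracks retained after frame filter")
    records = analyze_tracks(retained, thr)
    # replicates emptied by the filter are dropped implicitly; warn per group
    summary = summarize_groups(records, holm=holm)
    if excluded:
        summary.log.append(f"excluded {len(excluded)} tracks with <= {thr.min_frames_exclusive} frames")
    n_nonconv = int((~records["converged"]).sum())
    if n_nonconv:
        summary.log.append(f"{n_nonconv} non-converged fits labelled ambiguous")
    return records, summary


def confusion_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth mode vs assigned motion class (simulated data only)."""
    known = records[records["true_mode"] != ""]
    if known.empty:
        raise ValueError("no ground-truth labels in records")
    return pd.crosstab(known["true_mode"], known["motion_class"])
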