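"""Model/Results interface over the track-classification pipeline.

``TrackMotionModel`` is constructed from data (a long-format track table
or a list of trajectories) plus classification thresholds; ``fit()``
runs the MSD computation, the anomalous-diffusion fits and both
classifiers and returns a ``TrackMotionResults`` holding the per-track
estimates, the per-replicate fractions with their group means and SDs,
the Welch comparisons, and plotting/summary helpers.

Example
-------
>>> from trackmotion import simulate_study, TrackMotionModel
>>> table = simulate_study(tracks_per_mode=10, n_replicates=3)
>>> res = TrackMotionModel.from_dataframe(table).fit()
>>> print(res.summary())
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Thresholds
from .msd import compute_msd, fit_anomalous
from .pipeline import GroupSummary, confusion_matrix, run_pipeline
from .tracks import Trajectory, read_track_table, trajectories_to_dataframe


class TrackMotionModel:
    """Motion-type classification model for a set of particle tracks.

    Parameters
    ----------
    track_table : pandas.DataFrame
        Long-format table with columns ``track_id, frame, t_s, x_um,
        y_um`` and optional ``replicate_id, group, true_mode``.
    thresholds : Thresholds, optional
        Classification constants; defaults to the published values.
    """

    def __init__(self, track_table: pd.DataFrame, thresholds: Optional[Thresholds] = None):
        self.track_table = track_table
        self.thresholds = thresholds or Thresholds()

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, thresholds: Optional[Thresholds] = None):
        return cls(table, thresholds)

    @classmethod
    def from_trajectories(
        cls, trajectories: Iterable[Trajectory], thresholds: Optional[Thresholds] = None
    ):
        return cls(trajectories_to_dataframe(trajectories), thresholds)

    @classmethod
    def from_csv(cls, path, thresholds: Optional[Thresholds] = None):
        return cls(read_track_table(path), thresholds)

    def fit(self, holm: bool = False) -> "TrackMotionResults":
        """Classify every retained track and aggregate per replicate/group."""
        records, summary = run_pipeline(self.track_table, self.thresholds, holm=holm)
        return TrackMotionResults(self, records, summary)


class TrackMotionResults:
    """Fitted per-track classifications and replicate-level summaries.

    Attributes
    ----------
    records : pandas.DataFrame
        One row per retained track: fit parameters (A, alpha, B),
        motion class, ND/LMD (um), directionality.
    fractions : pandas.DataFrame
        Per (group, replicate, class family, class) fractions.
    group_stats : pandas.DataFrame
        Mean and SD of fractions across replicates per group.
    comparisons : pandas.DataFrame or None
        Per-class Welch's t and two-sided p (two-group designs).
    """

    def __init__(self, model: TrackMotionModel, records: pd.DataFrame, summary: GroupSummary):
        self.model = model
        self.records = records
        self._summary = summary

    @property
    def fractions(self) -> pd.DataFrame:
        return self._summary.fractions

    @property
    def group_stats(self) -> pd.DataFrame:
        return self._summary.group_stats

    @property
    def comparisons(self) -> Optional[pd.DataFrame]:
        return self._summary.comparisons

    @property
    def log(self) -> list[str]:
        return self._summary.log

    def confusion(self) -> pd.DataFrame:
        """Ground-truth mode vs motion class (requires true_mode labels)."""
        return confusion_matrix(self.records)

    def summary(self) -> str:
        """Plain-text report: fit counts, group fractions, comparisons."""
        from statsmodels.iolib.table import SimpleTable

        lines = ["Track motion classification results", "=" * 36]
        lines.append(f"Tracks analysed: {len(self.records)}")
        lines.append(f"Converged fits:  {int(self.records['converged'].sum())}")
        stats = self.group_stats.copy()
        stats["mean"] = stats["mean"].map("{:.3f}".format)
        stats["sd"] = stats["sd"].map("{:.3f}".format)
        tbl = SimpleTable(
            stats.to_numpy(),
            headers=list(stats.columns),
            title="Class fractions (mean +/- SD across replicates)",
        )
        lines.append(str(tbl))
        if self.comparisons is not None:
            comp = self.comparisons.copy()
            for col in comp.columns:
                if comp[col].dtype.kind == "f":
                    comp[col] = comp[col].map("{:.4g}".format)
            lines.append(str(SimpleTable(comp.to_numpy(), headers=list(comp.columns),
                                         title="Welch's t tests on per-replicate fractions")))
        for msg in self.log:
            lines.append(f"note: {msg}")
        return "\n".join(lines)

    def plot_fractions(self, family: str = "motion_class", ax=None):
        """Bar chart of group-mean class fractions with SD error bars."""
        import matplotlib.pyplot as plt

        stats = self.group_stats[self.group_stats["family"] == family]
        groups = sorted(stats["group"].unique())
        classes = list(dict.fromkeys(stats["class"]))
        if ax is None:
            _, ax = plt.subplots()
        width = 0.8 / max(len(groups), 1)
        xs = np.arange(len(classes))
        for i, g in enumerate(groups):
            sub = stats[stats["group"] == g].set_index("class").reindex(classes)
            ax.bar(xs + i * width, sub["mean"], width, yerr=sub["sd"], capsize=3, label=g)
        ax.set_xticks(xs + width * (len(groups) - 1) / 2)
        ax.set_xticklabels(classes)
        ax.set_ylabel("fraction of tracks")
        ax.set_title(family.replace("_", " "))
        ax.legend()
        return ax

    def plot_msd(self, track_id: str, ax=None):
        """MSD curve of one track with its fitted power law overlaid."""
        import matplotlib.pyplot as plt

        from .tracks import dataframe_to_trajectories

        match = [
            t for t in dataframe_to_trajectories(self.model.track_table)
            if t.track_id == track_id
        ]
        if not match:
            raise KeyError(f"track {track_id!r} not found")
        curve = compute_msd(match[0], self.model.thresholds.max_lag_fraction)
        fit = fit_anomalous(curve)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.lags, curve.msd, "o", label="time-averaged MSD")
        if fit.converged:
            tau = np.linspace(curve.lags[0], curve.lags[-1], 200)
            ax.plot(tau, fit.A * tau**fit.alpha + fit.B, "-",
                    label=rf"fit: $\alpha$ = {fit.alpha:.2f}")
        ax.set_xlabel(r"lag $\tau$ (s)")
        ax.set_ylabel(r"MSD ($\mu m^2$)")
        ax.set_title(track_id)
        ax.legend()
        return ax
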