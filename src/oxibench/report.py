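"""Nested-inset error map over the (%T, %MOD) signal space.

The report figure places one small inset per (%T, %MOD) grid point on
log-log master axes, with heart rate on the inset x-axis and SpO₂ on the
inset y-axis; each inset point is a (setting × profile) mean SpO₂ error,
drawn in red when it exceeds the 3% performance-concern threshold.  The
synthetic NICU epoch distribution is overlaid as a shaded density plus
epoch markers, situating the stress grid relative to clinically observed
signal conditions.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics_stats import ERROR_THRESHOLD_PCT
from .nicu_reference import NicuEpoch, density_grid

__all__ = ["plot_error_map"]

_INSET_TAG = "oxibench_inset"


def _add_insets(fig, ax, sub: pd.DataFrame, threshold: float) -> int:
    """One inset per (%T, %MOD) point; returns the inset count."""
    t_vals = np.sort(sub["t_pct"].unique())
    mod_vals = np.sort(sub["mod_pct"].unique())
    # inset size: a fixed fraction of the master axes, anchored with its
    # lower-left vertex at the (%T, %MOD) coordinates
    n_insets = 0
    for t in t_vals:
        for m in mod_vals:
            cell = sub[(sub["t_pct"] == t) & (sub["mod_pct"] == m)]
            if len(cell) == 0:
                continue
            x0, y0 = ax.transData.transform((t, m))
            fx, fy = fig.transFigure.inverted().transform((x0, y0))
            ia = fig.add_axes([fx, fy, 0.055, 0.055], label=f"{_INSET_TAG}:{t}:{m}")
            colors = np.where(cell["mean_error"] > threshold, "red", "0.4")
            ia.scatter(cell["hr_bpm"], cell["spo2_pct"], c=colors, s=4)
            ia.set_xticks([])
            ia.set_yticks([])
            for spine in ia.spines.values():
                spine.set_linewidth(0.4)
            n_insets += 1
    return n_insets


def plot_error_map(
    metrics: pd.DataFrame,
    epochs: list[NicuEpoch] | None = None,
    threshold: float = ERROR_THRESHOLD_PCT,
    out_path: str | Path | None = None,
    max_epoch_markers: int = 400,
):
    """Draw the nested-inset error map, one panel per device profile.

    ``metrics`` is the per-(setting × profile) table from
    :func:`oxibench.metrics_stats.aggregate_metrics`.  Returns the figure.
    """
    required = {"t_pct", "mod_pct", "spo2_pct", "hr_bpm", "profile", "mean_error"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValidationError(f"metrics table missing columns: {sorted(missing)}")
    profiles = sorted(metrics["profile"].unique())
    fig, axes = plt.subplots(
        1, len(profiles), figsize=(7.5 * len(profiles), 6.5), squeeze=False
    )
    for ax, profile in zip(axes[0], profiles):
        sub = metrics[metrics["profile"] == profile]
        ax.set_xscale("log")
        ax.set_yscale("log")
        t_vals = np.sort(sub["t_pct"].unique())
        mod_vals = np.sort(sub["mod_pct"].unique())
        ax.set_xlim(t_vals.min() / 2.5, max(t_vals.max() * 4, 40))
        ax.set_ylim(mod_vals.min() / 2.5, max(mod_vals.max() * 3, 9))
        ax.set_xlabel("%T")
        ax.set_ylabel("%MOD")
        ax.set_title(f"mean SpO2 error map: {profile}")
        if epochs:
            mass, t_edges, mod_edges = density_grid(epochs)
            ax.pcolormesh(
                t_edges, mod_edges, mass.T, cmap="Blues", alpha=0.6, shading="auto"
            )
            step = max(1, len(epochs) // max_epoch_markers)
            shown = epochs[::step]
            ax.scatter(
                [e.t_median for e in shown],
                [e.mod_median for e in shown],
                marker="v", s=8, c="0.5", alpha=0.5, label="synthetic NICU epochs",
            )
            ax.legend(loc="upper right", fontsize=7)
        fig.canvas.draw()  # fix data->figure transforms before inset placement
        _add_insets(fig, ax, sub, threshold)
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig


def count_insets(fig) -> int:
    """Number of per-(%T, %MOD) insets in a figure from :func:`plot_error_map`."""
    return sum(1 for a in fig.axes if str(a.get_label()).startswith(_INSET_TAG))
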