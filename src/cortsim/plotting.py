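"""Simple summary plots for simulated datasets and scenario tables."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .expression import ObservedDataset

__all__ = ["summary_panels", "sweep_heatmap", "group_curves_plot"]


def summary_panels(
    dataset: ObservedDataset,
    marker_times: Optional[Sequence[float]] = None,
    path=None,
):
    """Three-panel overview of one simulation run.

    (A) downsampled observed points, (B) full observed curves per event,
    (C) rank order of each individual's curve value over time. Vertical
    dashed lines mark ``marker_times`` (defaults to the observed fixed
    times when the design was fixed).
    """
    fig, axes = plt.subplots(3, 1, figsize=(7, 10), sharex=True)
    obs = dataset.observed
    if marker_times is None:
        counts = obs["time_min"].value_counts()
        if len(counts) <= 10:
            marker_times = sorted(counts.index)
        else:
            marker_times = []

    for (ind, _), grp in obs.groupby(["individual_id", "event_id"]):
        axes[0].plot(
            grp["time_min"], grp["value"], "o-", alpha=0.4, markersize=3
        )
    axes[0].set_ylabel("measured (ng/µl)")
    axes[0].set_title("downsampled dataset")

    curves = dataset.event_curves
    if curves is not None:
        for (_, _), grp in curves.groupby(["individual_id", "event_id"]):
            axes[1].plot(grp["time_min"], grp["value"], alpha=0.3, lw=0.8)
        axes[1].set_ylabel("response (ng/µl)")
        axes[1].set_title("full observed response curves")

        first = curves[curves["event_id"] == curves["event_id"].min()]
        wide = first.pivot(
            index="time_min", columns="individual_id", values="value"
        )
        ranks = wide.rank(axis=1)
        for col in ranks.columns:
            axes[2].plot(ranks.index, ranks[col], alpha=0.5, lw=0.8)
        axes[2].set_ylabel("rank")
        axes[2].set_title("rank order through time")
    axes[2].set_xlabel("minutes since stressor onset")
    for ax in axes:
        for t in marker_times:
            ax.axvline(t, ls="--", color="grey", lw=0.8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def sweep_heatmap(table: pd.DataFrame, path=None):
    """Heatmaps of mean R² by (max_sd, speed_sd), one panel per peak mean."""
    peaks = sorted(table["peak_mean"].unique())
    fig, axes = plt.subplots(
        1, len(peaks), figsize=(4 * len(peaks), 3.5), squeeze=False
    )
    for ax, peak in zip(axes[0], peaks):
        sub = table[table["peak_mean"] == peak]
        pivot = sub.pivot_table(
            index="max_sd", columns="speed_sd", values="r2", aggfunc="mean"
        ).sort_index(ascending=False)
        im = ax.imshow(
            pivot.to_numpy(), aspect="auto", vmin=0, vmax=1, cmap="viridis"
        )
        ax.set_xticks(range(len(pivot.columns)), pivot.columns)
        ax.set_yticks(range(len(pivot.index)), pivot.index)
        ax.set_xlabel("speed SD (min)")
        ax.set_ylabel("max SD (ng/µl)")
        ax.set_title(f"average peak at {peak:g} min")
        fig.colorbar(im, ax=ax, label="R²")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def group_curves_plot(estimates: dict, truths: dict, path=None):
    """Estimated vs true group-mean curves, one line pair per group.

    ``estimates``/``truths`` map group name -> DataFrame with columns
    time_min, estimate (and optional lower/upper) / true mean array.
    """
    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = {"control": "tab:blue", "treatment": "tab:orange"}
    for group, est in estimates.items():
        c = colors.get(group)
        ax.plot(
            est["time_min"], est["estimate"], "--", color=c,
            label=f"{group} (estimate)",
        )
        if {"lower", "upper"} <= set(est.columns):
            ax.fill_between(
                est["time_min"], est["lower"], est["upper"],
                color=c, alpha=0.2,
            )
        truth = truths[group]
        ax.plot(
            truth["time_min"], truth["value"], "-", color=c,
            label=f"{group} (true)",
        )
    ax.set_xlabel("minutes since stressor onset")
    ax.set_ylabel("glucocorticoid (ng/µl)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
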