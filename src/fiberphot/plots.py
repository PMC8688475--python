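"""Static figure export (PNG/SVG) for traces, PSTHs, and group averages."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .group import GroupResult
from .psth import PsthResult

__all__ = ["plot_trace", "plot_psth", "plot_heatmap", "plot_group", "save_figure"]


def save_figure(fig, out_base: Path, formats=("png",)) -> list[Path]:
    """Save one figure as PNG and/or SVG next to ``out_base``."""
    written = []
    for ext in formats:
        path = Path(f"{out_base}.{ext}")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        written.append(path)
    plt.close(fig)
    return written


def plot_trace(ts, title: str = "", ylabel: str = "value"):
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(ts.timestamps, ts.values, lw=0.5, color="k")
    ax.set(xlabel="time (s)", ylabel=ylabel, title=title)
    return fig

def plot_psth(psth: PsthResult, show_trials: bool = True):
    """Mean z-score with SEM band, optionally with individual trials."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if show_trials:
        ax.plot(psth.time, psth.trials.T, color="0.8", lw=0.5)
    ax.fill_between(
        psth.time, psth.mean - psth.sem, psth.mean + psth.sem,
        color="k", alpha=0.25, lw=0,
    )
    ax.plot(psth.time, psth.mean, color="k", lw=1.5)
    ax.axvline(0.0, color="r", ls="--", lw=0.8)
    ax.set(xlabel="time from event (s)", ylabel="z-score", title=psth.event_name)
    return fig


def plot_heatmap(psth: PsthResult):
    """All trials chronologically, one row each."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        psth.trials, aspect="auto", origin="upper",
        extent=[psth.time[0], psth.time[-1], psth.n_trials, 0],
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label="z-score")
    ax.set(xlabel="time from event (s)", ylabel="trial", title=psth.event_name)
    return fig


def plot_group(group: GroupResult):
    """Per-session means (thin) with the group mean ± SEM (bold)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, row in enumerate(group.session_means):
        ax.plot(group.time, row, lw=0.7, alpha=0.6, label=group.session_ids[i])
    ax.fill_between(
        group.time, group.group_mean - group.group_sem,
        group.group_mean + group.group_sem, color="k", alpha=0.25, lw=0,
    )
    ax.plot(group.time, group.group_mean, color="k", lw=2, label="group mean")
    ax.axvline(0.0, color="r", ls="--", lw=0.8)
    ax.legend(fontsize=7)
    ax.set(xlabel="time from event (s)", ylabel="z-score", title=group.event_name)
    return fig
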