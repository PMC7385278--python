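"""Figure exports: longitudinal time courses, stacked aeration
fractions, and stacked severity-class bars."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_COMPARTMENT_COLORS = {
    "hyper": "#9ecae1",
    "normo": "#3182bd",
    "poor": "#de2d26",
    "non": "#636363",
}
_SEVERITY_COLORS = {"mild": "#a1d99b", "moderate": "#fdae6b", "severe": "#de2d26"}


def plot_timecourse(timecourse: pd.DataFrame, path: str | Path, compartment: str = "poor"):
    """Group-mean ± s.e.m. of one aeration compartment over imaging days.

    ``timecourse`` is the long table from :func:`aeration_timecourse`.
    """
    sub = timecourse[timecourse["compartment"] == compartment]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group, g in sub.groupby("group"):
        g = g.sort_values("day")
        ax.errorbar(g["day"], g["mean"], yerr=g["sem"], marker="o", capsize=3, label=group)
    ax.set_xlabel("day after first challenge")
    ax.set_ylabel(f"fraction {compartment}-aerated")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_stacked_fractions(profiles_long: pd.DataFrame, path: str | Path):
    """Stacked per-animal aeration fractions (long table from
    :func:`profiles_to_frame`, one bar per animal-day)."""
    wide = profiles_long.pivot_table(
        index=["animal_id", "day"], columns="compartment", values="fraction"
    ).reset_index()
    labels = [f"{a}\nd{d}" for a, d in zip(wide["animal_id"], wide["day"])]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(labels)), 3.5))
    bottom = None
    for comp in ("hyper", "normo", "poor", "non"):
        if comp not in wide:
            continue
        vals = wide[comp].to_numpy()
        ax.bar(labels, vals, bottom=bottom, label=comp, color=_COMPARTMENT_COLORS[comp])
        bottom = vals if bottom is None else bottom + vals
    ax.set_ylabel("fraction of lung volume")
    ax.legend(frameon=False, ncol=4, fontsize=8)
    ax.tick_params(axis="x", labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_severity_stacked(severity: pd.DataFrame, path: str | Path):
    """Stacked severity-class frequencies per group/day (table with
    freq_mild / freq_moderate / freq_severe columns)."""
    labels = [f"{g}\nd{d}" for g, d in zip(severity["group"], severity["day"])]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(labels)), 3.5))
    bottom = None
    for cls in ("mild", "moderate", "severe"):
        vals = severity[f"freq_{cls}"].to_numpy()
        ax.bar(labels, vals, bottom=bottom, label=cls, color=_SEVERITY_COLORS[cls])
        bottom = vals if bottom is None else bottom + vals
    ax.set_ylabel("frequency")
    ax.legend(frameon=False, ncol=3)
    ax.tick_params(axis="x", labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
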