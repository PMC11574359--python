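"""Matplotlib figures for distributions, box stats and dose-response curves."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .assays import VesiculationResult
from .distributions import BoxStats, SizeDistribution, smooth_distribution


def plot_distributions(
    dists: Sequence[SizeDistribution],
    path: str | Path,
    smooth_window: int | None = 7,
    title: str = "",
) -> None:
    """Overlay size distributions (optionally display-smoothed)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for dist in dists:
        shown = smooth_distribution(dist, smooth_window) if smooth_window else dist
        name = dist.label or dist.channel or ""
        ax.plot(shown.bin_centres, shown.concentration, label=name)
    ax.set_xlabel("hydrodynamic diameter (nm)")
    ax.set_ylabel("concentration (particles/ml)")
    if title:
        ax.set_title(title)
    if any(d.label or d.channel for d in dists):
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_box_stats(groups: Mapping[str, Sequence[BoxStats]], path: str | Path, title: str = "") -> None:
    """Mode-centred box plots, one box per replicate set."""
    fig, ax = plt.subplots(figsize=(1.2 * max(len(groups), 2) + 1, 4))
    for i, (name, stats) in enumerate(groups.items()):
        for b in stats:
            ax.add_patch(
                plt.Rectangle((i - 0.3, b.lower), 0.6, b.upper - b.lower, fill=False, edgecolor="C0")
            )
            ax.hlines(b.mode, i - 0.3, i + 0.3, color="C3")
    ax.set_xticks(range(len(groups)), list(groups))
    ax.set_ylabel("hydrodynamic diameter (nm)")
    ax.relim()
    ax.autoscale_view()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dose_response(results: Mapping[str, VesiculationResult], path: str | Path, title: str = "") -> None:
    """Marker-bin concentration vs dose for one or more proteins."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, res in results.items():
        ax.plot(res.doses, res.metric, marker="o", label=name)
    ax.set_xlabel("dose (uM)")
    ax.set_ylabel("82.5-nm-bin concentration (particles/ml)")
    if len(results) > 1:
        ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
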