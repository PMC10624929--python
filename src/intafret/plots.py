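"""Figure export: transition-density and post-synchronized heatmaps,
overlaid FRET histograms."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ensemble import FretHistogram, PostSyncHistogram, TransitionDensity

__all__ = ["plot_transition_density", "plot_post_sync", "plot_fret_histograms"]


def plot_transition_density(tdp: TransitionDensity, path: str | Path, vmax: Optional[float] = None):
    fig, ax = plt.subplots(figsize=(4.2, 4))
    m = ax.pcolormesh(tdp.edges, tdp.edges, tdp.counts.T, cmap="viridis", vmax=vmax)
    ax.set_xlabel("initial FRET")
    ax.set_ylabel("final FRET")
    ax.set_title(f"{tdp.total} transitions")
    fig.colorbar(m, ax=ax, label="counts")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_post_sync(psh: PostSyncHistogram, path: str | Path, fret_max: float = 0.6):
    fig, ax = plt.subplots(figsize=(5, 3.2))
    m = ax.pcolormesh(psh.time_edges, psh.fret_edges, psh.counts.T, cmap="magma")
    ax.set_ylim(0, fret_max)
    ax.set_xlabel("time since injection (s)")
    ax.set_ylabel("FRET")
    fig.colorbar(m, ax=ax, label="counts")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fret_histograms(
    hists: Sequence[FretHistogram],
    labels: Sequence[str],
    path: str | Path,
    fret_max: float = 0.6,
):
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for hist, label in zip(hists, labels):
        ax.step(hist.centers, hist.counts, where="mid", label=label)
    ax.set_xlim(0, fret_max)
    ax.set_xlabel("FRET")
    ax.set_ylabel("normalized counts" if any(h.pseudo_norm for h in hists) else "counts")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
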