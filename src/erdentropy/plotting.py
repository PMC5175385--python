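"""Schematic topographic maps of per-channel statistics."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .montage import Montage
from .stats import ChannelStatMap

__all__ = ["topomap_figure"]


def topomap_figure(
    montage: Montage,
    cmap: ChannelStatMap,
    title: str = "",
    path: str | Path | None = None,
):
    """Scatter the per-channel statistic on the 2-D layout.

    Significant channels (FDR-adjusted p below alpha) are ring-marked.
    Returns the matplotlib figure; saves to ``path`` if given.
    """
    idx = [montage.index(ch) for ch in cmap.channels]
    xy = montage.layout[idx]
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=cmap.statistic, s=220, cmap="RdBu_r")
    sig = cmap.significant
    if sig.any():
        ax.scatter(
            xy[sig, 0], xy[sig, 1], s=330, facecolors="none",
            edgecolors="k", linewidths=1.6,
        )
    for (x, y), ch in zip(xy, cmap.channels):
        ax.annotate(ch, (x, y), ha="center", va="center", fontsize=6)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.75)
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig
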