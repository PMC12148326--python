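"""Visual QC helpers: rose plots, origin-referenced traces, flow quivers."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .datatypes import TrackSet, VectorField
from .trackstats import displacement_traces, rose_histogram


def plot_rose(
    tracks: TrackSet, n_bins: int = 16, mode: str = "per-track",
    path: str | Path | None = None,
):
    """Circular histogram of movement directions (posterior = 0°, CCW)."""
    counts, edges = rose_histogram(tracks, n_bins=n_bins, mode=mode)
    centers = np.deg2rad((edges[:-1] + edges[1:]) / 2.0)
    width = 2 * np.pi / n_bins
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.bar(centers, counts, width=width, bottom=0.0, edgecolor="k", alpha=0.8)
    ax.set_title(f"direction of cell movement ({mode})")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_traces(tracks: TrackSet, path: str | Path | None = None):
    """Per-cell traces relative to each cell's origin (µm)."""
    traces = displacement_traces(tracks)
    fig, ax = plt.subplots(figsize=(5, 4))
    for xy in traces.values():
        ax.plot(xy[:, 0], -xy[:, 1], lw=0.8)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlabel("x displacement (µm, posterior →)")
    ax.set_ylabel("y displacement (µm)")
    ax.set_title("traces relative to origin")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_quiver(field: VectorField, path: str | Path | None = None):
    """Quiver rendering of one flow field (valid cells only)."""
    gx, gy = np.meshgrid(field.grid_x, field.grid_y)
    m = field.valid
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.quiver(
        gx[m], gy[m], field.vx[m], -field.vy[m], angles="xy",
        scale_units="xy", color="tab:blue",
    )
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_title(f"flow, frames {field.frame_pair[0]}→{field.frame_pair[1]}")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
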