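"""Basic plots: tissue snapshots, volume trajectories, sweep heatmaps.

Matplotlib figures only; callers save or show them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .lattice import CANCER, DEAD, HEALTHY, MCC, Tissue, voronoi_polygons

CELL_COLOURS = {HEALTHY: "0.8", CANCER: "tab:orange", MCC: "tab:blue",
                DEAD: "tab:red"}


def plot_tissue(tissue: Tissue, ax=None, show_polygons: bool = False):
    """Cell map: healthy grey, cancer orange, MCC blue, dead red; empty
    space (disintegrated cells) is simply white."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    if show_polygons:
        from matplotlib.patches import Polygon as MplPolygon

        for poly, t in zip(voronoi_polygons(tissue), tissue.cell_type):
            if poly.is_empty:
                continue
            ax.add_patch(MplPolygon(np.asarray(poly.exterior.coords),
                                    facecolor=CELL_COLOURS[t],
                                    edgecolor="white", linewidth=0.2))
    else:
        for t, c in CELL_COLOURS.items():
            m = tissue.cell_type == t
            ax.plot(tissue.positions[m, 0], tissue.positions[m, 1], ".",
                    color=c, markersize=3)
    xmin, xmax, ymin, ymax = tissue.bounds
    ax.set_xlim(xmin, xmax)
    ax.set_ylim(ymin, ymax)
    ax.set_aspect("equal")
    ax.set_xlabel("x (model units)")
    ax.set_ylabel("y (model units)")
    return ax


def plot_volume_series(series_list, labels=None, ax=None):
    """Tumour-volume trajectories (time_h vs volume_mm3) for one or more
    recorded runs."""
    if ax is None:
        _, ax = plt.subplots()
    for i, s in enumerate(series_list):
        label = labels[i] if labels else None
        ax.plot(s["time_h"] / 24.0, s["volume_mm3"], label=label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("tumour volume (mm$^3$)")
    if labels:
        ax.legend()
    return ax


def plot_sweep_heatmap(sweep_df, value="final_volume", ax=None):
    """Placement x dose heatmap of the mean of ``value`` over replicates."""
    pivot = sweep_df.pivot_table(index="dose_ug", columns="d_m_mm",
                                 values=value, aggfunc="mean")
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto",
                   cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), [f"{c:g}" for c in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{i:g}" for i in pivot.index])
    ax.set_xlabel("placement distance (mm)")
    ax.set_ylabel("dose (ug)")
    plt.colorbar(im, ax=ax, label=value)
    return ax
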