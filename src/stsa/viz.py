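"""Figure rendering for survival curves and spatiotemporal maps.

Presentation layer only: every figure has a CSV/JSON twin written by
the CLI, so nothing downstream ever reads pixels.  Conventions follow
the analysis: hazard/CA heat maps put spatial bins on the vertical
axis (bottom-up) and time bins on the horizontal; survival panels grey
the sparse right tail beyond the 5% mask and mark the median with a
dotted vertical line; undefined CA cells render as background, never
as zero.
"""

from __future__ import annotations

import numpy as np
import matplotlib
import matplotlib.pyplot as plt

from .spatiotemporal import StsaMaps, OccupancyGrid, log_view
from .survival import SurvivalCurves, median_rt, mask_from

__all__ = ["render_survival_panel", "render_map", "render_occupancy",
           "render_average_trajectories"]


def _grey_tail(ax, curves, mask_bin):
    if mask_bin is not None:
        w = curves.grid.bin_width_ms
        ax.axvspan(mask_bin * w, curves.grid.display_span_ms,
                   color="0.85", zorder=0)


def render_survival_panel(curves_by_condition: dict, mask_threshold: float = 0.05):
    """h(t), S(t), ca(t) panel for a set of conditions (one figure).

    Lines break at undefined ca bins; greyed spans mark bins past the
    point where fewer than ``mask_threshold`` of trials remain.
    """
    if not curves_by_condition:
        raise ValueError("no curves to render")
    fig, axes = plt.subplots(3, 1, figsize=(7, 8), sharex=True)
    for key, c in curves_by_condition.items():
        n = c.grid.n_display_bins
        t = c.bin_upper_edges_ms[:n]
        lab = " ".join(map(str, key)) if isinstance(key, tuple) else str(key)
        axes[0].step(t, c.h[:n], where="post", label=lab)
        axes[1].step(t, c.S[:n], where="post", label=lab)
        axes[2].plot(t, c.ca[:n], label=lab)   # NaN gaps break the line
        med = median_rt(c)
        if med is not None:
            axes[1].axvline(med, linestyle=":", linewidth=1)
        mask = mask_from(c, mask_threshold)
        _grey_tail(axes[0], c, mask)
        _grey_tail(axes[2], c, mask)
    for ax, name in zip(axes, ["h(t)", "S(t)", "ca(t)"]):
        ax.set_ylabel(name)
        ax.set_ylim(-0.05, 1.05)
    axes[2].set_xlabel("time (ms)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    return fig


def render_map(maps: StsaMaps, kind: str = "hazard", ax=None, vmax=None):
    """Heat map of H or CA; spatial bins bottom-up, time rightward.

    ``vmax`` lets a caller share one color scale across scaled
    condition maps (after scaling the global max is exactly 1).
    Undefined CA cells are masked and take the background color.
    """
    if kind not in ("hazard", "ca"):
        raise ValueError("kind must be 'hazard' or 'ca'")
    arr = maps.display("H" if kind == "hazard" else "CA")
    data = np.ma.masked_invalid(arr)
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 3))
    else:
        fig = ax.figure
    cmap = matplotlib.colormaps["viridis"].copy()
    cmap.set_bad(color="white")
    w = maps.grid.temporal.bin_width_ms
    extent = [0, arr.shape[1] * w / 1000.0, 0, maps.grid.total_distance_m]
    im = ax.imshow(data, origin="lower", aspect="auto", cmap=cmap,
                   vmin=0, vmax=vmax, extent=extent)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("|x| (m)")
    ax.set_title(f"{kind.upper()} {' '.join(map(str, maps.label))}".strip())
    fig.colorbar(im, ax=ax)
    return fig


def render_occupancy(grid: OccupancyGrid, log: bool = True, ax=None):
    """Stage-2 occupancy heat map, log10(count+1) by default."""
    if grid.counts is None:
        raise ValueError("occupancy grid has no counts")
    data = log_view(grid.counts) if log else grid.counts
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4))
    else:
        fig = ax.figure
    extent = [0, grid.n_temporal * grid.t_bin_ms / 1000.0,
              grid.x_min_m, grid.x_max_m]
    im = ax.imshow(data, origin="lower", aspect="auto", extent=extent,
                   cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("x (m)")
    fig.colorbar(im, ax=ax,
                 label="log10(visits + 1)" if log else "visits")
    return fig


def render_average_trajectories(avg_by_condition: dict):
    """Stage-0 averaged trajectories, one line per condition."""
    if not avg_by_condition:
        raise ValueError("nothing to render")
    fig, ax = plt.subplots(figsize=(7, 4))
    for key, df in avg_by_condition.items():
        lab = " ".join(map(str, key)) if isinstance(key, tuple) else str(key)
        ax.plot(df["t_ms"] / 1000.0, df["x_mean_m"], label=lab)
    ax.axhline(0, color="0.7", linewidth=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean x (m)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
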