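"""Time x energy heat-map density grids for temporal dietary patterns.

For each cluster, a grid over time-of-day and per-event energy holds the
percentage of cluster members reporting at least one eating event in the
cell; a participant counts at most once per cell.  Events are binned by
their discrete (time, energy) occasion values, not the expanded
minute-level series, matching how intake amounts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .recall import RecallDay

__all__ = ["GridConfig", "DensityGrid", "compute_density", "render_heatmap", "grid_to_frame"]


@dataclass(frozen=True)
class GridConfig:
    """Bin layout: hourly time bins and 100-kcal energy bins by default."""

    time_bin_min: int = 60
    energy_bin_kcal: float = 100.0
    energy_max_kcal: float = 4000.0

    @property
    def time_edges(self) -> np.ndarray:
        return np.arange(0, 1440 + self.time_bin_min, self.time_bin_min, dtype=float)

    @property
    def energy_edges(self) -> np.ndarray:
        return np.arange(
            0, self.energy_max_kcal + self.energy_bin_kcal, self.energy_bin_kcal
        )


@dataclass
class DensityGrid:
    """Per-cluster percentage grids, shape (n_energy_bins, n_time_bins)."""

    clusters: list
    values: dict  # cluster -> 2-D array of percentages (or NaN for empty cluster)
    config: GridConfig = field(default_factory=GridConfig)


def compute_density(recalls, labels, grid_config: GridConfig = GridConfig()) -> DensityGrid:
    """Percentage of each cluster reporting an event per (time, energy) cell."""
    labels = np.asarray(labels)
    if len(labels) != len(recalls):
        raise ValueError("labels must cover recalls")
    t_edges = grid_config.time_edges
    e_edges = grid_config.energy_edges
    clusters = sorted(np.unique(labels).tolist())
    values = {}
    for c in clusters:
        members = [r for r, lab in zip(recalls, labels) if lab == c]
        grid = np.zeros((len(e_edges) - 1, len(t_edges) - 1))
        if not members:
            values[c] = np.full_like(grid, np.nan)
            continue
        for r in members:
            tb = np.digitize(r.times, t_edges) - 1
            eb = np.digitize(r.energies, e_edges) - 1
            ok = (tb >= 0) & (tb < grid.shape[1]) & (eb >= 0) & (eb < grid.shape[0])
            cells = set(zip(eb[ok].tolist(), tb[ok].tolist()))  # once per cell
            for ei, ti in cells:
                grid[ei, ti] += 1.0
        values[c] = 100.0 * grid / len(members)
    return DensityGrid(clusters=clusters, values=values, config=grid_config)


def grid_to_frame(grid: DensityGrid) -> pd.DataFrame:
    """Long-format export: cluster, time_bin, energy_bin, pct."""
    rows = []
    for c in grid.clusters:
        v = grid.values[c]
        for ei in range(v.shape[0]):
            for ti in range(v.shape[1]):
                rows.append((c, ti, ei, v[ei, ti]))
    return pd.DataFrame(rows, columns=["cluster", "time_bin", "energy_bin", "pct"])


def render_heatmap(grid: DensityGrid, out_path) -> plt.Figure:
    """Write a one-panel-per-cluster raster heat map; darker = more members.

    Returns the figure (the colour scale tops out at the grid maximum).
    """
    k = len(grid.clusters)
    fig, axes = plt.subplots(1, k, figsize=(4 * k, 4), squeeze=False)
    finite_max = max(
        (np.nanmax(v) for v in grid.values.values() if np.isfinite(v).any()),
        default=0.0,
    )
    vmax = finite_max if finite_max > 0 else 1.0
    t_edges = grid.config.time_edges
    e_edges = grid.config.energy_edges
    im = None
    for ax, c in zip(axes[0], grid.clusters):
        v = np.nan_to_num(grid.values[c], nan=0.0)
        im = ax.imshow(
            v,
            origin="lower",
            aspect="auto",
            cmap="Greys",
            vmin=0.0,
            vmax=vmax,
            extent=(t_edges[0] / 60.0, t_edges[-1] / 60.0, e_edges[0], e_edges[-1]),
        )
        ax.set_title(f"Cluster {c}")
        ax.set_xlabel("Time of day (h)")
        ax.set_xticks(np.arange(0, 25, 6))
        ax.set_xticklabels([f"{h:02d}:00" for h in range(0, 25, 6)])
    axes[0][0].set_ylabel("Energy (kcal)")
    cbar = fig.colorbar(im, ax=axes[0].tolist(), shrink=0.9)
    cbar.set_label("% of cluster reporting intake")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return fig
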