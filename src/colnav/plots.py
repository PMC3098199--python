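"""Image export for occupancy grids and rate maps."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def save_occupancy_png(grid: np.ndarray, path, bin_cm: float = 5.0) -> None:
    """Occupancy grid (seconds per bin) as a heat map image."""
    fig, ax = plt.subplots(figsize=(4, 5))
    masked = np.ma.masked_where(grid.T == 0, grid.T)
    im = ax.imshow(masked, origin="lower", cmap="viridis",
                   extent=(0, grid.shape[0] * bin_cm,
                           0, grid.shape[1] * bin_cm))
    fig.colorbar(im, ax=ax, label="occupancy (s)")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_rate_map_png(rate_map_df, path, bin_cm: float = 5.0) -> None:
    """Rate map (as produced by :func:`colnav.analysis.rate_map`) image."""
    nx_ = int(rate_map_df["cx"].max()) + 1
    ny = int(rate_map_df["cy"].max()) + 1
    grid = np.full((nx_, ny), np.nan)
    for row in rate_map_df.itertuples(index=False):
        grid[int(row.cx), int(row.cy)] = row.rate_hz
    fig, ax = plt.subplots(figsize=(4, 5))
    im = ax.imshow(np.ma.masked_invalid(grid.T), origin="lower",
                   cmap="inferno",
                   extent=(0, nx_ * bin_cm, 0, ny * bin_cm))
    fig.colorbar(im, ax=ax, label="rate (Hz)")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
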