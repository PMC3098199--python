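"""Simulated hippocampal place-cell population.

Provides the redundant, distributed spatial input code: Gaussian place fields
with centers tiled densely along corridor midlines.  Fields are fixed from
t=0 (cortical learning is assumed to begin only once the hippocampal code is
stable) and noise-free; Poisson spike synthesis for spike-based statistics
lives in :mod:`colnav.analysis`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .maze import Maze, NODE_SPACING

DEFAULT_SIGMA = 7.5      # cm; place-field width, smaller than level-1 fields
DEFAULT_PEAK_RATE = 10.0  # Hz
DEFAULT_SPACING = 5.0    # cm between field centers along the midline


@dataclass
class PlaceCellPopulation:
    """Gaussian place fields with a common width and peak rate."""

    centers: np.ndarray          # (n, 2) cm
    sigma: float = DEFAULT_SIGMA
    peak_rate: float = DEFAULT_PEAK_RATE
    rng_seed: int = 0
    _node_cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.centers)

    def rates(self, position) -> np.ndarray:
        """Firing rate of every cell at ``position`` (Hz)."""
        p = np.asarray(position, dtype=float)
        d2 = np.sum((self.centers - p) ** 2, axis=1)
        return self.peak_rate * np.exp(-d2 / (2.0 * self.sigma ** 2))

    def rates_at_node(self, node) -> np.ndarray:
        """Cached rate vector for a lattice node (positions are discrete)."""
        key = (round(node[0], 6), round(node[1], 6))
        out = self._node_cache.get(key)
        if out is None:
            out = self.rates(key)
            self._node_cache[key] = out
        return out

    def to_csv(self) -> str:
        buf = StringIO()
        buf.write(f"# sigma={self.sigma} peak_rate={self.peak_rate} "
                  f"seed={self.rng_seed}\n")
        pd.DataFrame(self.centers, columns=["x_cm", "y_cm"]).to_csv(
            buf, index=False)
        return buf.getvalue()


def seed_place_cells(maze: Maze, spacing: float = DEFAULT_SPACING,
                     sigma: float = DEFAULT_SIGMA,
                     peak_rate: float = DEFAULT_PEAK_RATE,
                     seed: int = 0) -> PlaceCellPopulation:
    """Tile field centers every ``spacing`` cm along corridor midlines.

    Centers get <=1 cm of seeded uniform jitter perpendicular to nothing in
    particular (both axes), which keeps them inside the 10 cm wide corridor.
    Deterministic for a fixed seed.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    seg_lengths = [abs(x1 - x0) + abs(y1 - y0)
                   for (x0, y0), (x1, y1) in maze.segments]
    if spacing > min(l for l in seg_lengths if l > 0):
        raise ValueError("spacing exceeds the shortest corridor segment")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    for (x0, y0), (x1, y1) in maze.segments:
        length = abs(x1 - x0) + abs(y1 - y0)
        n = int(length // spacing)
        ux, uy = np.sign(x1 - x0), np.sign(y1 - y0)
        for k in range(n):  # half-open: start inclusive, end exclusive
            d = k * spacing
            cx, cy = x0 + ux * d, y0 + uy * d
            jx, jy = rng.uniform(-1.0, 1.0, size=2)
            centers.append((cx + jx, cy + jy))
    return PlaceCellPopulation(centers=np.asarray(centers), sigma=sigma,
                               peak_rate=peak_rate, rng_seed=seed)


def place_cell_rates(pop: PlaceCellPopulation, position) -> np.ndarray:
    return pop.rates(position)
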