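"""2D kernel density maps of displacement vectors.

Displacement vectors (Δx, Δy) of microsaccades or drift episodes jointly
encode displacement magnitude and direction; their 2D kernel density,
discretised into a 22-level contour plot with the lowest level omitted,
visualises the direction/magnitude structure per fixation target, polarity
and participant.

The estimator is a Gaussian product kernel with per-axis Silverman
bandwidth h_j = σ_j · n^(−1/6) (the d=2 rule-of-thumb).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["DensityGrid", "kde2d", "contour_levels", "plot_density",
           "write_grid", "read_grid"]


@dataclass
class DensityGrid:
    """A KDE evaluated on a regular Cartesian grid.

    ``density`` has shape (len(y), len(x)) with rows indexed by y, and
    integrates to ≈ 1 over the grid when the extents capture the mass.
    """

    x: np.ndarray  # grid coordinates, deg
    y: np.ndarray
    density: np.ndarray  # (ny, nx), deg⁻²
    bandwidth: tuple[float, float]  # (hx, hy), deg

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def integral(self) -> float:
        return float(self.density.sum() * self.cell_area)


def _silverman(v: np.ndarray) -> float:
    # d=2 rule of thumb: h = sigma * n^(-1/(d+4))
    return float(np.std(v, ddof=1) * len(v) ** (-1.0 / 6.0))


def kde2d(
    vectors: np.ndarray,
    extent: tuple[float, float, float, float] | None = None,
    resolution: int = 128,
    bandwidth: tuple[float, float] | None = None,
) -> DensityGrid:
    """Gaussian product-kernel density of 2D displacement vectors.

    ``extent`` is (xmin, xmax, ymin, ymax); the default pads the data range
    by three bandwidths per side so the grid captures essentially all mass.
    Fewer than 2 vectors or zero spread on an axis raise
    :class:`DegenerateGeometryError`.
    """
    p = np.asarray(vectors, dtype=float).reshape(-1, 2)
    n = len(p)
    if n < 2:
        raise DegenerateGeometryError("kde2d needs at least 2 vectors")
    if bandwidth is None:
        hx, hy = _silverman(p[:, 0]), _silverman(p[:, 1])
    else:
        hx, hy = bandwidth
    if hx <= 0 or hy <= 0:
        raise DegenerateGeometryError("zero spread: cannot form a density")
    if extent is None:
        extent = (
            p[:, 0].min() - 3 * hx,
            p[:, 0].max() + 3 * hx,
            p[:, 1].min() - 3 * hy,
            p[:, 1].max() + 3 * hy,
        )
    gx = np.linspace(extent[0], extent[1], resolution)
    gy = np.linspace(extent[2], extent[3], resolution)
    # separable kernel: density = KY @ KX.T / n
    kx = np.exp(-0.5 * ((gx[:, None] - p[None, :, 0]) / hx) ** 2) / (
        hx * np.sqrt(2 * np.pi)
    )
    ky = np.exp(-0.5 * ((gy[:, None] - p[None, :, 1]) / hy) ** 2) / (
        hy * np.sqrt(2 * np.pi)
    )
    density = ky @ kx.T / n
    return DensityGrid(x=gx, y=gy, density=density, bandwidth=(hx, hy))


def contour_levels(grid: DensityGrid, n_levels: int = 22) -> np.ndarray:
    """Equally spaced density thresholds in (0, max]; strictly increasing.

    Rendering omits the lowest level for clarity.
    """
    peak = float(grid.density.max())
    if peak <= 0:
        raise DegenerateGeometryError("flat-zero grid has no contour levels")
    return np.linspace(0.0, peak, n_levels + 1)[1:]


def plot_density(grid: DensityGrid, n_levels: int = 22, ax=None):
    """Filled contour plot of the density with the lowest level not shown."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    levels = contour_levels(grid, n_levels)
    cs = ax.contourf(grid.x, grid.y, grid.density, levels=levels)
    ax.set_xlabel("Δx (deg)")
    ax.set_ylabel("Δy (deg)")
    ax.set_aspect("equal")
    return cs


def write_grid(grid: DensityGrid, matrix_path: str | Path, sidecar_path: str | Path) -> None:
    """Write the density matrix as delimited text plus a JSON sidecar."""
    np.savetxt(matrix_path, grid.density, delimiter=",")
    meta = {
        "x_min": float(grid.x[0]),
        "x_max": float(grid.x[-1]),
        "y_min": float(grid.y[0]),
        "y_max": float(grid.y[-1]),
        "resolution_x": len(grid.x),
        "resolution_y": len(grid.y),
        "bandwidth": [grid.bandwidth[0], grid.bandwidth[1]],
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def read_grid(matrix_path: str | Path, sidecar_path: str | Path) -> DensityGrid:
    density = np.loadtxt(matrix_path, delimiter=",")
    meta = json.loads(Path(sidecar_path).read_text())
    return DensityGrid(
        x=np.linspace(meta["x_min"], meta["x_max"], meta["resolution_x"]),
        y=np.linspace(meta["y_min"], meta["y_max"], meta["resolution_y"]),
        density=density,
        bandwidth=tuple(meta["bandwidth"]),
    )
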