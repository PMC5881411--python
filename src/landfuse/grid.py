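"""Regular geographic grids in WGS84 longitude/latitude.

The target product lives on a global 10 arc-second grid anchored at integer
multiples of the cell size from (-180, +90).  Rows run north to south, all
indices are 0-based and cell extents are half-open, so a point on a shared
edge belongs to the cell to its south-east.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ARCSEC_PER_DEGREE = 3600.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid.

    Parameters
    ----------
    cell_size
        Angular cell extent in arc-seconds (same in both axes).
    origin_lon, origin_lat
        Degrees of the grid's north-west corner.
    n_rows, n_cols
        Grid shape; row 0 is northernmost.
    """

    cell_size: float
    origin_lon: float
    origin_lat: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def step(self) -> float:
        """Cell size in degrees."""
        return self.cell_size / ARCSEC_PER_DEGREE

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    # -- coordinates --------------------------------------------------------

    def cell_center(self, row, col):
        """(lon, lat) of cell centers; accepts scalars or arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.step
        lat = self.origin_lat - (row + 0.5) * self.step
        return lon, lat

    def cell_centers(self):
        """Meshgrid of all cell-center (lon, lat), each of shape (n_rows, n_cols)."""
        rows = np.arange(self.n_rows)
        cols = np.arange(self.n_cols)
        lon, lat = self.cell_center(rows[:, None], cols[None, :])
        return np.broadcast_to(lon, self.shape).copy(), np.broadcast_to(lat, self.shape).copy()

    def locate(self, lon, lat):
        """Map points to (row, col); half-open cells, edge points go south-east.

        Returns integer arrays; points outside the extent get index -1 in the
        offending axis.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # tiny forward nudge (1e-9 cells ~ 1e-12 deg) so points computed to
        # lie exactly on a shared edge land in the south-east cell despite
        # floating-point rounding
        col = np.floor((lon - self.origin_lon) / self.step + 1e-9).astype(np.int64)
        row = np.floor((self.origin_lat - lat) / self.step + 1e-9).astype(np.int64)
        col = np.where((col >= 0) & (col < self.n_cols), col, -1)
        row = np.where((row >= 0) & (row < self.n_rows), row, -1)
        return row, col

    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) in degrees."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.step,
            self.origin_lon + self.n_cols * self.step,
            self.origin_lat,
        )

    def same_grid(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
        )


def global_aligned_grid(
    cell_size: float, west: float, north: float, n_rows: int, n_cols: int
) -> GridSpec:
    """Grid anchored at integer multiples of ``cell_size`` from (-180, +90).

    ``west``/``north`` are snapped outward (west and north) so the requested
    corner is covered, matching the registration of the global 10 arc-second
    products the fused map targets.
    """
    step = cell_size / ARCSEC_PER_DEGREE
    i = np.floor((west - (-180.0)) / step)
    j = np.floor((90.0 - north) / step)
    return GridSpec(cell_size, -180.0 + i * step, 90.0 - j * step, n_rows, n_cols)
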