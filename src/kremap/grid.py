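"""Raster geometry: the analysis grid and gridded population counts.

Every stage of the pipeline (disaggregation, kernel ratio estimation,
significance testing, hotspot delineation) evaluates on one shared
:class:`GridSpec`.  Cells are square, in projected units (metres); row 0 is
the northernmost row, matching the row order of ESRI ASCII grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["GridSpec", "PopulationGrid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a square-celled raster in a projected CRS.

    Parameters
    ----------
    origin_x, origin_y
        Projected coordinates (m) of the lower-left corner of the grid.
    cell_size
        Side length of a cell (m); cells are square.
    n_rows, n_cols
        Grid dimensions; row 0 is the top (northernmost) row.
    crs_label
        Free-text label of the projected CRS; carried through output
        metadata, never interpreted.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_label: str = "local-projected"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def extent_area_km2(self) -> float:
        return self.n_cells * self.cell_area_km2

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return (x, y)

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (n_rows, n_cols) with cell-center coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def flat_centers(self) -> np.ndarray:
        """Cell centers as an (n_cells, 2) array in row-major (C) order."""
        xx, yy = self.center_coords()
        return np.column_stack([xx.ravel(), yy.ravel()])

    def pairwise_center_distances(self) -> np.ndarray:
        """Dense (n_cells, n_cells) Euclidean distance matrix between centers.

        Intended for grids of a few thousand cells; kernels and bandwidths
        are built from it.
        """
        pts = self.flat_centers()
        return cdist(pts, pts)


@dataclass
class PopulationGrid:
    """Non-negative person counts on a :class:`GridSpec`.

    ``stratum`` labels an age stratum when the grid has been split by block
    group age structure; ``None`` means total ambient population (the
    LandScan-style background).
    """

    spec: GridSpec
    counts: np.ndarray
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.spec.shape:
            raise ValueError(
                f"counts shape {self.counts.shape} != grid shape {self.spec.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("population counts must be non-negative")
        # a zero total is legal for an age stratum (degenerate age mix);
        # operations that need people (bandwidths, UCMC) check it themselves

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def with_counts(self, counts: np.ndarray, stratum: Optional[str] = None) -> "PopulationGrid":
        return PopulationGrid(self.spec, counts, stratum)
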