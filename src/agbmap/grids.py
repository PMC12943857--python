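"""Grid geometry and named raster stacks.

All rasters in the pipeline live on a shared planar metric grid (projected
CRS assumed; distances are Euclidean in map units). The grid follows the
usual north-up raster convention: the origin is the outer corner of cell
(0, 0), columns increase eastward and rows increase southward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridGeometry", "RasterStack"]


@dataclass(frozen=True)
class GridGeometry:
    """Affine geometry of a north-up raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; both at least 1.
    cell_size
        Square cell edge in metres, > 0.
    origin_x, origin_y
        Map coordinates of the outer (north-west) corner of cell (0, 0).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width(self) -> float:
        """East-west extent in metres."""
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        """North-south extent in metres."""
        return self.n_rows * self.cell_size

    def cell_center(self, row, col):
        """Map coordinates (x, y) of cell centers. Vectorized."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def cell_index(self, x, y):
        """(row, col) of the cell containing map point(s) (x, y).

        Points exactly on a cell boundary belong to the cell to the
        south-east of the boundary, matching ``floor`` semantics.
        """
        x = np.asarray(x)
        y = np.asarray(y)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(np.int64)
        return row, col

    def contains(self, x, y):
        """Boolean mask of points inside the grid extent."""
        row, col = self.cell_index(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def all_centers(self):
        """Center coordinates of every cell as two (n_rows, n_cols) arrays."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.cell_center(rows, cols)


@dataclass
class RasterStack:
    """Ordered collection of co-registered 2D bands.

    Bands are float arrays; missing data is carried as NaN internally and
    mapped to an explicit nodata value only at the I/O boundary. Any derived
    band is NaN wherever an input band is NaN (nodata propagates).
    """

    grid: GridGeometry
    bands: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.bands.items():
            self._check_band(name, arr)
        # preserve insertion order, coerce to float64 views only when needed
        self.bands = {k: np.asarray(v, dtype=float) for k, v in self.bands.items()}

    def _check_band(self, name: str, arr) -> None:
        arr = np.asarray(arr)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"band {name!r} has shape {arr.shape}, grid is {self.grid.shape}"
            )

    def add(self, name: str, arr) -> None:
        if name in self.bands:
            raise ValueError(f"band {name!r} already present")
        self._check_band(name, arr)
        self.bands[name] = np.asarray(arr, dtype=float)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise KeyError(f"band {name!r} not in stack; have {self.names}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.bands

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.bands]
        if missing:
            raise KeyError(f"missing band(s): {', '.join(missing)}")

    def copy(self) -> "RasterStack":
        return RasterStack(self.grid, {k: v.copy() for k, v in self.bands.items()})

    def update(self, other: "RasterStack") -> None:
        """Merge bands from another stack on the same grid."""
        if other.grid != self.grid:
            raise ValueError("stacks are on different grids")
        for name, arr in other.bands.items():
            self.add(name, arr)
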