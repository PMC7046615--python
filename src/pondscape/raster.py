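"""Georeferenced regular grids.

A :class:`GridRaster` is the carrier of every gridded quantity in the
pipeline: climate variables, land-cover covariates, suitability
probabilities, the habitat suitability index (HSI), resistance and
connectivity surfaces.  Grids are row-major and north-up: row 0 is the
northern edge, and cell ``(r, c)`` covers the half-open square
``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]`` where ``(x0, y0)``
is the top-left corner and ``s`` the cell size in metres.  Coordinates are
planar (projected); nodata is carried as NaN.

Persistence uses the ESRI ASCII grid format (``.asc``), a plain-text
georeferenced raster format readable by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["GridRaster", "FrameMismatchError", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


class FrameMismatchError(ValueError):
    """Two rasters do not share origin / cell size / shape."""


@dataclass
class GridRaster:
    """A 2-D real field on a regular, north-up, projected grid.

    Parameters
    ----------
    values : ndarray of float, shape (rows, cols)
        Cell values; NaN marks nodata.
    origin : (float, float)
        ``(x, y)`` of the grid's top-left corner, in metres.
    cell_size : float
        Cell side length in metres; must be positive.
    crs_tag : str
        Opaque identifier of the projected reference system.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 50.0
    crs_tag: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- frame geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) arrays of shape (rows, cols) of every cell center."""
        x0, y0 = self.origin
        s = self.cell_size
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = x0 + (cols + 0.5) * s
        ys = y0 - (rows + 0.5) * s
        return np.meshgrid(xs, ys)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        s = self.cell_size
        return (x0 + (col + 0.5) * s, y0 - (row + 0.5) * s)

    def index_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """Map point coordinates to (row, col) under the half-open cell rule."""
        x0, y0 = self.origin
        s = self.cell_size
        col = np.floor((np.asarray(x) - x0) / s).astype(int)
        row = np.floor((y0 - np.asarray(y)) / s - 1e-12).astype(int)
        # points exactly on the top edge belong to row 0
        row = np.clip(row, 0, None)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        x0, y0 = self.origin
        s = self.cell_size
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= x0)
            & (x < x0 + self.n_cols * s)
            & (y <= y0)
            & (y > y0 - self.n_rows * s)
        )

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Values at an (n, 2) array of (x, y) points."""
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        row, col = self.index_of(points[:, 0], points[:, 1])
        row = np.clip(row, 0, self.n_rows - 1)
        col = np.clip(col, 0, self.n_cols - 1)
        return self.values[row, col]

    # -- frame comparison ----------------------------------------------
    def same_frame(self, other: "GridRaster", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= atol
            and abs(self.origin[0] - other.origin[0]) <= atol
            and abs(self.origin[1] - other.origin[1]) <= atol
        )

    def require_same_frame(self, other: "GridRaster") -> None:
        if not self.same_frame(other):
            raise FrameMismatchError(
                f"raster frames differ: {self.shape}@{self.origin}/{self.cell_size} "
                f"vs {other.shape}@{other.origin}/{other.cell_size}"
            )

    def with_values(self, values: np.ndarray) -> "GridRaster":
        """Same frame, new values."""
        out = replace(self, values=np.asarray(values, dtype=float))
        if out.values.shape != self.values.shape:
            raise ValueError("with_values must preserve shape")
        return out

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2


def write_ascii_grid(raster: GridRaster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (text; NaN -> NODATA_value)."""
    path = Path(path)
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    x0, y0 = raster.origin
    yll = y0 - raster.n_rows * raster.cell_size
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, crs_tag: str = "local-metric") -> GridRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    vals = np.atleast_2d(vals).reshape(nrows, ncols)
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return GridRaster(vals, origin=origin, cell_size=cell, crs_tag=crs_tag)
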