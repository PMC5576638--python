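"""Projected raster grids and ESRI ASCII grid I/O.

Grids are plain 2-D float arrays in a projected coordinate system with
metric units.  Missing cells are ``NaN`` internally and a ``nodata_value``
sentinel on disk.  The ESRI ASCII format is used because it is plain text
and round-trips exactly at the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ClimateGrid", "read_ascii_grid", "write_ascii_grid"]

_NODATA_DEFAULT = -9999.0


@dataclass
class ClimateGrid:
    """A single-band raster of mean summer temperature (or any scalar).

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values in °C; ``NaN`` marks nodata.  Row 0 is the *northern*
        edge, matching the ESRI ASCII convention.
    x_origin, y_origin : float
        Projected coordinates (m) of the grid's west edge and *north* edge.
    cell_size : float
        Cell edge length in metres; cells are square.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates, shape = grid shape."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edges."""
        return (
            self.x_origin,
            self.y_origin - self.nrows * self.cell_size,
            self.x_origin + self.ncols * self.cell_size,
            self.y_origin,
        )

    def contains_point(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x <= xmax and ymin <= y <= ymax

    def copy_with(self, values: np.ndarray) -> "ClimateGrid":
        return replace(self, values=np.asarray(values, dtype=float))

    def clip(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "ClimateGrid":
        """Subset to cells whose *centers* fall inside the box (edges inclusive)."""
        X, Y = self.cell_centers()
        col_keep = (X[0] >= xmin) & (X[0] <= xmax)
        row_keep = (Y[:, 0] >= ymin) & (Y[:, 0] <= ymax)
        if not col_keep.any() or not row_keep.any():
            raise ValueError("clip box contains no cell centers")
        r0, r1 = np.flatnonzero(row_keep)[[0, -1]]
        c0, c1 = np.flatnonzero(col_keep)[[0, -1]]
        return ClimateGrid(
            values=self.values[r0 : r1 + 1, c0 : c1 + 1].copy(),
            x_origin=self.x_origin + c0 * self.cell_size,
            y_origin=self.y_origin - r0 * self.cell_size,
            cell_size=self.cell_size,
            crs=self.crs,
        )


def write_ascii_grid(grid: ClimateGrid, path, nodata_value: float = _NODATA_DEFAULT) -> None:
    vals = np.where(np.isnan(grid.values), nodata_value, grid.values)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_origin - grid.nrows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path, crs: str = "local-metric") -> ClimateGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (nrows, ncols):
        raise ValueError(f"grid body {vals.shape} does not match header ({nrows}, {ncols})")
    nodata = header.get("nodata_value", _NODATA_DEFAULT)
    vals = np.where(vals == nodata, np.nan, vals)
    cell = header["cellsize"]
    return ClimateGrid(
        values=vals,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        crs=crs,
    )
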