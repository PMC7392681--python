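"""Minimal north-up raster grid container and plain-text raster I/O.

Rasters are plain 2-D float arrays paired with a :class:`Grid` describing a
north-up, square-pixel geometry (row 0 is the northern edge).  No-data is
represented by NaN in memory.  Files round-trip through the ESRI ASCII grid
format, which is text-based and widely readable by GIS software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "write_ascii_grid", "read_ascii_grid"]


@dataclass(frozen=True)
class Grid:
    """North-up raster geometry with square pixels.

    Parameters
    ----------
    nrows, ncols : int
        Raster shape.
    x0, y0 : float
        Coordinates of the lower-left corner of the grid, in the units of
        ``crs`` (metres for the local metric system used throughout).
    px : float
        Pixel size (metres). 25 m matches L-band SAR mosaic products.
    crs : str
        Free-text label of the coordinate reference system.
    """

    nrows: int
    ncols: int
    x0: float = 0.0
    y0: float = 0.0
    px: float = 25.0
    crs: str = "local-metric"

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def extent_area_ha(self) -> float:
        return self.nrows * self.ncols * self.px**2 / 1e4

    def xy(self, row, col):
        """Pixel-center coordinates of (row, col); row 0 at the top."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.px
        y = self.y0 + (self.nrows - row - 0.5) * self.px
        return x, y

    def rowcol(self, x, y):
        """Row/col of the pixel containing (x, y)."""
        x = np.asarray(x)
        y = np.asarray(y)
        col = np.floor((x - self.x0) / self.px).astype(int)
        row = self.nrows - 1 - np.floor((y - self.y0) / self.px).astype(int)
        return row, col

    def contains(self, x, y):
        x = np.asarray(x)
        y = np.asarray(y)
        w = self.ncols * self.px
        h = self.nrows * self.px
        return (x >= self.x0) & (x < self.x0 + w) & (y >= self.y0) & (y < self.y0 + h)

    def coord_mesh(self):
        """(x, y) pixel-center coordinate arrays of the full grid."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.xy(rows, cols)


def write_ascii_grid(path, array: np.ndarray, grid: Grid, nodata: float = -9999.0) -> None:
    arr = np.asarray(array, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError(f"array shape {arr.shape} does not match grid {grid.shape}")
    out = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
        f"xllcorner {grid.x0}\nyllcorner {grid.y0}\n"
        f"cellsize {grid.px}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path) -> tuple[np.ndarray, Grid]:
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    grid = Grid(
        nrows=int(meta["nrows"]),
        ncols=int(meta["ncols"]),
        x0=meta["xllcorner"],
        y0=meta["yllcorner"],
        px=meta["cellsize"],
    )
    arr = arr.reshape(grid.shape)
    arr[arr == meta["nodata_value"]] = np.nan
    return arr, grid
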