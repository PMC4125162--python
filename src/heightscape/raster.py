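"""Gridded canopy-height rasters and plain-text raster I/O.

The raster model is deliberately small: a 2-D float array of heights in
meters (0 = non-vegetated), a boolean nodata mask, a square cell size and
the planar coordinate of the top-left corner.  Grids are row-major and
0-based; cell (r, c) has its center at
``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``,
i.e. y decreases with row index as in north-up imagery.

Rasters round-trip through the ESRI ASCII grid format (a plain-text format
that survives text-only archiving); single-band float TIFF export is
available when :mod:`tifffile` is importable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

#: Sentinel written to ASCII grids for masked cells.
NODATA_VALUE = -9999.0


@dataclass
class HeightRaster:
    """A gridded vegetation-height map.

    Parameters
    ----------
    values : ndarray of float
        Heights in meters; non-vegetated cells are 0.  Values under the
        nodata mask are ignored (and zeroed on construction).
    nodata_mask : ndarray of bool, optional
        True where no observation exists.  Defaults to all-False.
    cell_size : float
        Cell edge length in meters (square cells, equal-area projection
        assumed).
    origin : (float, float)
        Planar (x, y) of the grid's top-left corner.
    """

    values: np.ndarray
    nodata_mask: np.ndarray | None = None
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=np.float32, copy=True)
        if self.values.ndim != 2:
            raise ValueError("height raster must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.array(self.nodata_mask, dtype=bool, copy=True)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata mask shape differs from value grid")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values[self.nodata_mask] = 0.0
        if np.any(self.values[~self.nodata_mask] < 0):
            raise ValueError("heights must be non-negative outside nodata")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean grid, True where an observation exists."""
        return ~self.nodata_mask

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate vectors for columns and rows."""
        rows, cols = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(rows) + 0.5) * self.cell_size
        return xs, ys

    def center(self) -> tuple[float, float]:
        """Planar coordinate of the raster's geometric center."""
        rows, cols = self.values.shape
        x0, y0 = self.origin
        return (x0 + cols * self.cell_size / 2.0, y0 - rows * self.cell_size / 2.0)

    # -- I/O ------------------------------------------------------------
    def to_ascii(self, path: str | os.PathLike) -> None:
        """Write as ESRI ASCII grid (nodata cells become NODATA_VALUE)."""
        rows, cols = self.values.shape
        x0, y0 = self.origin
        out = np.where(self.nodata_mask, NODATA_VALUE, self.values)
        header = (
            f"ncols {cols}\n"
            f"nrows {rows}\n"
            f"xllcorner {x0:.6f}\n"
            f"yllcorner {y0 - rows * self.cell_size:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {NODATA_VALUE:.1f}"
        )
        np.savetxt(path, out, fmt="%.4f", header=header, comments="")

    @classmethod
    def from_ascii(cls, path: str | os.PathLike) -> "HeightRaster":
        """Read an ESRI ASCII grid written by :meth:`to_ascii` (or GIS tools)."""
        meta: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(6):
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                }:
                    meta[parts[0].lower()] = float(parts[1])
                    pos = fh.tell()
                else:
                    break
            fh.seek(pos)
            grid = np.loadtxt(fh, dtype=np.float64)
        grid = np.atleast_2d(grid)
        nodata = meta.get("nodata_value", NODATA_VALUE)
        mask = np.isclose(grid, nodata)
        cell = meta.get("cellsize", 30.0)
        nrows = int(meta.get("nrows", grid.shape[0]))
        x0 = meta.get("xllcorner", 0.0)
        y0 = meta.get("yllcorner", 0.0) + nrows * cell
        grid = np.where(mask, 0.0, grid)
        return cls(values=grid, nodata_mask=mask, cell_size=cell, origin=(x0, y0))

    def to_tiff(self, path: str | os.PathLike) -> None:
        """Write as single-band float32 TIFF (requires tifffile)."""
        import tifffile

        out = np.where(self.nodata_mask, np.float32(NODATA_VALUE), self.values)
        tifffile.imwrite(path, out.astype(np.float32))
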