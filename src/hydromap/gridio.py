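"""Plain-text raster I/O and grid geometry.

Rasters live on regular planar grids in km. :class:`AsciiGrid` stores values
with row index 0 at the *south* edge (y increasing with row index) and
converts to the ESRI ASCII convention (first file row = north) on write, so
in-memory indexing matches the maths while files interoperate with standard
GIS tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["AsciiGrid", "GridSpec"]

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: lower-left corner, cell size, shape."""

    xll: float
    yll: float
    cell_size: float
    nx: int
    ny: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise InvalidArgumentError("cell_size must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise InvalidArgumentError("grid must have at least one cell")

    @classmethod
    def from_extent(cls, extent, cell_size: float) -> "GridSpec":
        x0, y0, x1, y1 = extent
        nx = max(1, int(np.ceil((x1 - x0) / cell_size)))
        ny = max(1, int(np.ceil((y1 - y0) / cell_size)))
        return cls(xll=x0, yll=y0, cell_size=cell_size, nx=nx, ny=ny)

    def x_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.nx) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.yll + (np.arange(self.ny) + 0.5) * self.cell_size

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_centers(), self.y_centers())


@dataclass
class AsciiGrid:
    """A value layer on a regular grid; row 0 is the southernmost row."""

    values: np.ndarray
    xll: float
    yll: float
    cell_size: float
    nodata: float = NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise InvalidArgumentError("cell_size must be > 0")

    @property
    def spec(self) -> GridSpec:
        ny, nx = self.values.shape
        return GridSpec(self.xll, self.yll, self.cell_size, nx, ny)

    def x_centers(self) -> np.ndarray:
        return self.spec.x_centers()

    def y_centers(self) -> np.ndarray:
        return self.spec.y_centers()

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell lookup of point locations (clamped to the grid)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ny, nx = self.values.shape
        ix = np.clip(((x - self.xll) / self.cell_size).astype(int), 0, nx - 1)
        iy = np.clip(((y - self.yll) / self.cell_size).astype(int), 0, ny - 1)
        return self.values[iy, ix]

    def write(self, path) -> None:
        """Write in ESRI ASCII grid format (north row first)."""
        ny, nx = self.values.shape
        header = (
            f"ncols {nx}\n"
            f"nrows {ny}\n"
            f"xllcorner {self.xll:.6f}\n"
            f"yllcorner {self.yll:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {self.nodata:.1f}\n"
        )
        body = np.flipud(np.where(np.isnan(self.values), self.nodata, self.values))
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.6f")

    @classmethod
    def read(cls, path) -> "AsciiGrid":
        lines = Path(path).read_text().splitlines()
        meta = {}
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                meta[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        body = np.loadtxt(lines[i:])
        body = np.atleast_2d(body)
        nodata = meta.get("nodata_value", NODATA)
        values = np.flipud(body)
        values = np.where(values == nodata, np.nan, values)
        return cls(
            values=values,
            xll=meta["xllcorner"],
            yll=meta["yllcorner"],
            cell_size=meta["cellsize"],
            nodata=nodata,
        )
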