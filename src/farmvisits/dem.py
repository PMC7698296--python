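"""Digital elevation model handling on ESRI ASCII grids.

GPS altitude is reported against the same vertical datum as the DEM, so
altitude above ground at a fix is ``altitude_m - dem.elevation_at(x, y)``.
Elevation is interpolated bilinearly between cell centres; coordinates
outside the grid extent are reported as not covered rather than
extrapolated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AsciiGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class AsciiGrid:
    """A regular grid raster in ESRI ASCII (.asc) layout.

    ``values[0, :]`` is the northernmost row, matching the on-disk order.
    ``xll``/``yll`` locate the lower-left corner of the lower-left cell.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered area."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def covers(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def elevation_at(self, x, y) -> np.ndarray:
        """Bilinear interpolation between cell centres; edges are clamped.

        Raises ``ValueError`` if any point lies outside the grid extent.
        """
        scalar = np.ndim(x) == 0 and np.ndim(y) == 0
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if not np.all(self.covers(x, y)):
            raise ValueError("point(s) outside DEM extent")
        cs = self.cellsize
        # fractional column/row measured from the first cell centre;
        # rows are stored north-first so the row index runs opposite to y
        fx = (x - (self.xll + cs / 2.0)) / cs
        fy = ((self.yll + self.nrows * cs - cs / 2.0) - y) / cs
        fx = np.clip(fx, 0.0, self.ncols - 1.0)
        fy = np.clip(fy, 0.0, self.nrows - 1.0)
        j0 = np.clip(np.floor(fx).astype(int), 0, self.ncols - 2) if self.ncols > 1 else np.zeros_like(fx, dtype=int)
        i0 = np.clip(np.floor(fy).astype(int), 0, self.nrows - 2) if self.nrows > 1 else np.zeros_like(fy, dtype=int)
        tx = fx - j0
        ty = fy - i0
        j1 = np.minimum(j0 + 1, self.ncols - 1)
        i1 = np.minimum(i0 + 1, self.nrows - 1)
        v = self.values
        z = (
            v[i0, j0] * (1 - tx) * (1 - ty)
            + v[i0, j1] * tx * (1 - ty)
            + v[i1, j0] * (1 - tx) * ty
            + v[i1, j1] * tx * ty
        )
        return float(z[0]) if scalar else z


def read_ascii_grid(path: str | Path) -> AsciiGrid:
    text = Path(path).read_text()
    lines = text.splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(io.StringIO("\n".join(lines[i:])))
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared dimensions")
    return AsciiGrid(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: AsciiGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll:.6f}\n")
        fh.write(f"yllcorner {grid.yll:.6f}\n")
        fh.write(f"cellsize {grid.cellsize:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:.1f}\n")
        np.savetxt(fh, grid.values, fmt="%.3f")
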