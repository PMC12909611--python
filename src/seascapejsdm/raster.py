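"""Gridded raster container and ESRI ASCII grid I/O.

All rasters in the pipeline share one planar grid in projected metre
coordinates: a lower-left origin, a square cell size, and an ``(nrow, ncol)``
array stored with row 0 at the *top* (map convention).  Cell centres are the
reference points for every distance and neighbourhood computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Origin (lower-left corner), square cell size in metres, and shape."""

    x_origin: float
    y_origin: float
    cell_size: float
    nrow: int
    ncol: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.nrow < 1 or self.ncol < 1:
            raise ValueError("grid must have at least one cell")

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) centre coordinate arrays of shape (nrow, ncol)."""
        xs = self.x_origin + (np.arange(self.ncol) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(self.nrow)[::-1] + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def locate(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y)."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.y_origin) / self.cell_size))
        row = self.nrow - 1 - row_from_bottom
        if not (0 <= row < self.nrow and 0 <= col < self.ncol):
            raise ValueError(f"point ({x}, {y}) lies outside the grid")
        return row, col

    def matches(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.nrow == other.nrow
            and self.ncol == other.ncol
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class Raster:
    """A single-band raster: values plus an in-study (sea) mask."""

    geometry: GridGeometry
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.nrow, self.geometry.ncol):
            raise ValueError("value array shape does not match geometry")
        if self.mask is None:
            self.mask = np.ones_like(self.values, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match geometry")

    def aligned_with(self, other: "Raster") -> bool:
        return self.geometry.matches(other.geometry)


def write_ascii_grid(path, raster: Raster) -> None:
    """Write an ESRI ASCII grid; masked-out cells become the nodata value."""
    geom = raster.geometry
    vals = np.where(raster.mask, raster.values, NODATA)
    header = (
        f"ncols {geom.ncol}\n"
        f"nrows {geom.nrow}\n"
        f"xllcorner {geom.x_origin!r}\n"
        f"yllcorner {geom.y_origin!r}\n"
        f"cellsize {geom.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    geom = GridGeometry(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        nrow=int(header["nrows"]),
        ncol=int(header["ncols"]),
    )
    vals = np.atleast_2d(vals)
    nodata = header.get("nodata_value", NODATA)
    mask = vals != nodata
    return Raster(geometry=geom, values=np.where(mask, vals, 0.0), mask=mask)
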