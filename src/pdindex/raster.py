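"""Gridded population-density raster: in-memory container and ESRI ASCII grid I/O.

The grid convention throughout the package: ``values`` is a row-major matrix
with row 0 the northernmost row; ``origin_lon`` / ``origin_lat`` give the
upper-left (north-west) corner of the grid; cells are square with side
``cell_size`` in degrees.  A point belongs to the cell whose extent contains
it under the half-open rule ``[west, east) x (south, north]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import RasterExtentError, SchemaError

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class DensityRaster:
    """People-per-km2 grid (or any scalar field on the same convention)."""

    origin_lon: float
    origin_lat: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("raster values must be a 2-D matrix")
        if self.cell_size <= 0:
            raise SchemaError("raster cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of the full grid."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/column of the cell containing (lon, lat).

        West edges belong to the cell, east edges to the neighbour; north
        edges belong to the cell, south edges to the neighbour below.
        """
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((self.origin_lat - lat) / self.cell_size))
        # the grid's own northern boundary is included (half-open in -lat)
        if row == -0:
            row = 0
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise RasterExtentError(
                f"point (lon={lon}, lat={lat}) outside raster extent {self.extent}"
            )
        return row, col

    def lookup(self, lon: float, lat: float) -> float:
        row, col = self.cell_index(lon, lat)
        return float(self.values[row, col])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of cell-center longitudes (len n_cols) and latitudes (len n_rows)."""
        lons = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lats = self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return lons, lats


def write_ascii_grid(raster: DensityRaster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc). xllcorner/yllcorner is the lower-left corner."""
    lon_min, lat_min, _, _ = raster.extent
    lines = [
        f"ncols {raster.n_cols}",
        f"nrows {raster.n_rows}",
        f"xllcorner {float(lon_min)!r}",
        f"yllcorner {float(lat_min)!r}",
        f"cellsize {float(raster.cell_size)!r}",
        f"NODATA_value {float(raster.nodata)!r}",
    ]
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in raster.values)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_ascii_grid(path: str | Path) -> DensityRaster:
    """Parse an ESRI ASCII grid. Header keys are case-insensitive; NODATA optional."""
    text = Path(path).read_text().strip().splitlines()
    header: dict[str, float] = {}
    row_idx = 0
    for row_idx, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    missing = [k for k in _ASC_HEADER_KEYS if k not in header]
    if missing:
        raise SchemaError(f"{path}: .asc header missing keys {missing}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    values = np.loadtxt(text[row_idx:], ndmin=2)
    if values.shape != (n_rows, n_cols):
        raise SchemaError(
            f"{path}: grid body is {values.shape}, header says ({n_rows}, {n_cols})"
        )
    return DensityRaster(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        values=values,
        nodata=header.get("nodata_value", -9999.0),
    )
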