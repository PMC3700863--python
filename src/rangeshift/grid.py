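"""Geographic analysis grid and plain-text raster I/O.

Rasters are regular WGS84 lon/lat grids. Arrays are indexed ``[row, col]``
with row 0 at the *southern* edge, so cell centers are
``lon_min + (col + 0.5) * cell_size`` and ``lat_min + (row + 0.5) * cell_size``.
Cell membership uses half-open intervals ``[edge, edge + cell_size)``: a point
exactly on an interior edge belongs to the higher-index cell.

On-disk rasters are ESRI ASCII grids (``.asc``), which store rows north to
south; readers and writers flip accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic grid in decimal degrees (WGS84).

    Parameters
    ----------
    lon_min, lat_min
        Coordinates of the south-west corner (cell edge, not center).
    cell_size
        Cell edge length in degrees (2.5 arc-minutes = 1/24 degree).
    n_rows, n_cols
        Grid shape; rows count northward from ``lat_min``.
    """

    lon_min: float
    lat_min: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @classmethod
    def from_bounds(
        cls, lon_min: float, lon_max: float, lat_min: float, lat_max: float, cell_size: float
    ) -> "GridSpec":
        n_cols = int(round((lon_max - lon_min) / cell_size))
        n_rows = int(round((lat_max - lat_min) / cell_size))
        return cls(lon_min, lat_min, cell_size, n_rows, n_cols)

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell ``(row, col)``."""
        return (
            self.lon_min + (col + 0.5) * self.cell_size,
            self.lat_min + (row + 0.5) * self.cell_size,
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Containing cell of a point, or None if outside the grid.

        Half-open convention: a point on an interior edge falls in the
        higher-index cell; points on the north/east outer edge are outside.
        """
        col = int(np.floor((lon - self.lon_min) / self.cell_size))
        row = int(np.floor((lat - self.lat_min) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None

    def cos_lat_weights(self) -> np.ndarray:
        """Per-row cell-area weights proportional to cos(latitude of center).

        On a geographic grid the true cell area shrinks with latitude as
        cos(phi); at 36-42 N ignoring this distorts areas by several percent.
        """
        return np.cos(np.deg2rad(self.lat_centers()))


def write_ascii_grid(path: str | Path, grid: GridSpec, data: np.ndarray) -> None:
    """Write a 2D array as an ESRI ASCII grid; NaN becomes the NODATA value."""
    data = np.asarray(data, dtype=float)
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
    out = np.where(np.isnan(data), NODATA, data)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min!r}\n"
        f"yllcorner {grid.lat_min!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        # .asc rows run north to south; our row 0 is the southern edge
        np.savetxt(fh, out[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = np.atleast_2d(data).reshape(n_rows, n_cols)[::-1].copy()
    nodata = header.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    spec = GridSpec(
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return spec, data
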