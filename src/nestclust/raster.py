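"""Regular-grid raster container and ESRI ASCII grid I/O.

Grids are row-major ``float64`` arrays in projected planar meters.  Row 0 is
the *top* row of the map (ESRI ASCII convention); the ``origin`` is the
lower-left corner of the lower-left cell.  Cell centers define the traversal
nodes used for least-cost routing and the sample points used for zonal
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, ParseError

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    grid: np.ndarray              # (nrows, ncols), row 0 = northernmost
    origin: tuple[float, float]   # (x, y) of lower-left corner, meters
    cell_size: float              # meters
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise InvalidParameterError("raster grid must be 2-D")
        if self.cell_size <= 0:
            raise InvalidParameterError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def nrows(self) -> int:
        return self.grid.shape[0]

    @property
    def ncols(self) -> int:
        return self.grid.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded area."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def mask(self) -> np.ndarray:
        """Boolean array, True where data is valid."""
        return self.grid != self.nodata

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y); raises if outside."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row_from_bottom = int(np.floor((y - y0) / self.cell_size))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise InvalidParameterError(f"point ({x}, {y}) outside raster extent {self.bounds}")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 + (self.nrows - 1 - row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) arrays of shape (nrows, ncols) with every cell center."""
        x0, y0 = self.origin
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        xs = x0 + (cols + 0.5) * self.cell_size
        ys = y0 + (self.nrows - 1 - rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def value_at(self, x: float, y: float) -> float:
        r, c = self.cell_of(x, y)
        return float(self.grid[r, c])


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    path = Path(path)
    x0, y0 = raster.origin
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {y0!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.grid, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        try:
            grid = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: malformed grid body: {exc}") from exc
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ParseError(f"{path}: missing ASCII-grid header field {key!r}")
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ParseError(
            f"{path}: grid body {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return Raster(
        grid=grid,
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
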