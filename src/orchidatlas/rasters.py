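"""Minimal single-band raster container with ESRI ASCII grid I/O.

The pipeline only needs axis-aligned, square-cell rasters in geographic
coordinates (climate surfaces, biome maps, land masks), for which the plain
text ESRI ASCII grid format is sufficient and keeps every artifact
human-readable.  Rows are stored north-to-south, as in the file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999.0


@dataclass
class Raster:
    """A single-band grid. ``data[0, :]`` is the northernmost row.

    Parameters
    ----------
    data:
        2-D float array, shape ``(n_rows, n_cols)``.
    xll, yll:
        Coordinates of the lower-left corner of the lower-left cell.
    cellsize:
        Cell edge length (square cells), same units as ``xll``/``yll``.
    nodata:
        Sentinel for missing cells (ocean / outside the landmass).
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the full grid."""
        return (
            self.xll,
            self.yll,
            self.xll + self.n_cols * self.cellsize,
            self.yll + self.n_rows * self.cellsize,
        )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a value."""
        return ~np.isclose(self.data, self.nodata)

    def is_aligned_with(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    # ---- coordinate <-> index -------------------------------------------
    def index_of(self, x, y):
        """Containing-cell indices for point coordinates.

        Half-open cells, lower-edge inclusive; points on the extent's top or
        right edge are clamped into the last row/column so the extent is
        fully covered.  Returns ``(rows, cols, inside)`` arrays where
        ``rows`` counts from the northern edge (array order).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        min_x, min_y, max_x, max_y = self.extent
        inside = (x >= min_x) & (x <= max_x) & (y >= min_y) & (y <= max_y)
        cols = np.floor((x - self.xll) / self.cellsize).astype(int)
        rows_s = np.floor((y - self.yll) / self.cellsize).astype(int)
        cols = np.where(inside & (cols == self.n_cols), self.n_cols - 1, cols)
        rows_s = np.where(inside & (rows_s == self.n_rows), self.n_rows - 1, rows_s)
        rows = self.n_rows - 1 - rows_s
        rows = np.clip(rows, 0, self.n_rows - 1)
        cols = np.clip(cols, 0, self.n_cols - 1)
        return rows, cols, inside

    def value_at(self, x, y):
        """Containing-cell value lookup (no interpolation).

        Out-of-extent points get ``nodata``.
        """
        rows, cols, inside = self.index_of(x, y)
        vals = self.data[rows, cols]
        return np.where(inside, vals, self.nodata)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates, each shaped like ``data``."""
        cols = np.arange(self.n_cols)
        rows_s = np.arange(self.n_rows - 1, -1, -1)  # south-count per array row
        cx = self.xll + (cols + 0.5) * self.cellsize
        cy = self.yll + (rows_s + 0.5) * self.cellsize
        return np.meshgrid(cx, cy)


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.6g") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.xll!r}\n")
        fh.write(f"yllcorner {raster.yll!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        np.savetxt(fh, raster.data, fmt=fmt)


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"ASCII grid header missing {key}: {path}")
        data = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(
            f"ASCII grid body shape {data.shape} does not match header "
            f"({n_rows}, {n_cols}): {path}"
        )
    return Raster(
        data=data,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", NODATA_DEFAULT),
    )
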