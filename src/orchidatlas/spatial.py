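"""Cell lattices, richness surfaces, and area of occupancy (AOO).

Two grid modes cover the two cell sizes the analysis needs: plain
``geographic_degrees`` lattices (e.g. 0.5° richness maps) and
``equal_area_km`` lattices in which coordinates are first pushed through an
equal-area transform (default: cylindrical equal-area about the extent's
mid-latitude) before tiling, so that every cell represents the same ground
area — the basis of the 10 km x 10 km (100 km²) AOO counts.

Grid rows count from the southern origin upward (row 0 touches ``y0``);
cells are half-open ``[edge, edge + size)`` with the extent's upper
boundary closing the final row/column so the extent tiles exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import InputError
from .rasters import Raster

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

Transform = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


def identity_transform(x: np.ndarray, y: np.ndarray):
    """Pass-through "flat" transform: grid coordinates = input coordinates."""
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def cylindrical_equal_area(standard_parallel: float) -> Transform:
    """Lambert cylindrical equal-area, (lon, lat) degrees -> kilometres."""
    k = np.cos(np.radians(standard_parallel))
    if k <= 0:
        raise InputError(f"standard parallel {standard_parallel} gives no projection")

    def transform(lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = EARTH_RADIUS_KM * np.radians(lon) * k
        y = EARTH_RADIUS_KM * np.sin(np.radians(lat)) / k
        return x, y

    return transform


@dataclass
class GridSpec:
    """A rectangular cell lattice over (possibly transformed) coordinates."""

    x0: float
    y0: float
    dx: float
    dy: float
    n_cols: int
    n_rows: int
    mode: str = "geographic_degrees"  # or "equal_area_km"
    transform: Transform | None = None

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0 or self.n_cols < 1 or self.n_rows < 1:
            raise InputError("invalid grid spec")

    @property
    def cell_area(self) -> float:
        """Area of one cell in grid units squared (km² in equal-area mode)."""
        return self.dx * self.dy

    def apply_transform(self, x, y):
        if self.transform is None:
            return np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        return self.transform(x, y)

    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


def build_grid(
    extent: tuple[float, float, float, float],
    cell_size: float | tuple[float, float],
    mode: str = "geographic_degrees",
    transform: Transform | None = None,
    standard_parallel: float | None = None,
) -> GridSpec:
    """Tile ``extent`` with half-open cells of ``cell_size``.

    ``extent`` is (min_x, min_y, max_x, max_y) in input coordinates; in
    ``equal_area_km`` mode the corners are transformed first (default
    transform: cylindrical equal-area about the extent mid-latitude, or
    pass :func:`identity_transform` for synthetic flat geometry).  The
    number of cells is the ceiling of span / size; a cell size larger than
    the extent yields a single-cell grid with a logged warning.
    """
    min_x, min_y, max_x, max_y = extent
    if not (max_x > min_x and max_y > min_y):
        raise InputError(f"degenerate extent {extent}")
    dx, dy = cell_size if isinstance(cell_size, tuple) else (cell_size, cell_size)
    if dx <= 0 or dy <= 0:
        raise InputError(f"cell size must be positive, got {cell_size}")
    if mode not in {"geographic_degrees", "equal_area_km"}:
        raise InputError(f"unknown grid mode {mode!r}")

    if mode == "equal_area_km" and transform is None:
        mid_lat = 0.5 * (min_y + max_y)
        transform = cylindrical_equal_area(
            standard_parallel if standard_parallel is not None else mid_lat
        )
    if mode == "geographic_degrees":
        transform = transform  # honoured if explicitly provided

    if transform is not None:
        (x0, x1), (y0, y1) = (
            transform(np.array([min_x, max_x]), np.array([min_y, max_y]))
        )
        min_x, max_x = float(x0), float(x1)
        min_y, max_y = float(y0), float(y1)

    n_cols = max(1, int(np.ceil((max_x - min_x) / dx - 1e-12)))
    n_rows = max(1, int(np.ceil((max_y - min_y) / dy - 1e-12)))
    if (max_x - min_x) < dx or (max_y - min_y) < dy:
        logger.warning(
            "cell size %s larger than extent span; using a single-cell grid", cell_size
        )
    return GridSpec(
        x0=min_x, y0=min_y, dx=dx, dy=dy,
        n_cols=n_cols, n_rows=n_rows, mode=mode, transform=transform,
    )


def assign_cells(
    x, y, grid: GridSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Containing cell for each point: ``(rows, cols, inside)``.

    Rows count from the grid origin upward.  Boundary points belong to the
    cell whose lower edge they touch; points on the extent's upper edges
    are clamped into the final row/column.  Out-of-extent points get
    ``inside=False`` (and clamped indices that must not be used).
    """
    tx, ty = grid.apply_transform(x, y)
    x_max = grid.x0 + grid.n_cols * grid.dx
    y_max = grid.y0 + grid.n_rows * grid.dy
    inside = (tx >= grid.x0) & (tx <= x_max) & (ty >= grid.y0) & (ty <= y_max)
    cols = np.floor((tx - grid.x0) / grid.dx).astype(int)
    rows = np.floor((ty - grid.y0) / grid.dy).astype(int)
    cols = np.where(inside & (cols == grid.n_cols), grid.n_cols - 1, cols)
    rows = np.where(inside & (rows == grid.n_rows), grid.n_rows - 1, rows)
    cols = np.clip(cols, 0, grid.n_cols - 1)
    rows = np.clip(rows, 0, grid.n_rows - 1)
    n_out = int(np.size(inside) - np.count_nonzero(inside))
    if n_out:
        logger.info("%d records fall outside the grid extent and are excluded", n_out)
    return rows, cols, inside


@dataclass
class RichnessGrid:
    """Per-cell distinct species and genus counts on one lattice."""

    grid: GridSpec
    species: np.ndarray  # int, shape (n_rows, n_cols)
    genus: np.ndarray

    def __post_init__(self) -> None:
        if self.species.shape != self.grid.shape() or self.genus.shape != self.grid.shape():
            raise InputError("richness layers do not match the grid shape")

    @property
    def ratio(self) -> np.ndarray:
        return diversification_surface(self)


def richness_per_cell(
    frame: pd.DataFrame, grid: GridSpec, rank: str = "species"
) -> np.ndarray:
    """Distinct-taxon count per cell for one rank (species or genus).

    Repeated records of a taxon in a cell count once.  Records outside the
    extent are excluded (logged by :func:`assign_cells`).  An empty table
    gives an all-zero layer.
    """
    column = {"species": "scientificName", "genus": "genus"}.get(rank)
    if column is None:
        raise InputError(f"unknown rank {rank!r}")
    counts = np.zeros(grid.shape(), dtype=int)
    if len(frame) == 0:
        return counts
    rows, cols, inside = assign_cells(
        frame["decimalLongitude"].to_numpy(float),
        frame["decimalLatitude"].to_numpy(float),
        grid,
    )
    sub = pd.DataFrame(
        {"row": rows[inside], "col": cols[inside],
         "taxon": frame.loc[inside, column].to_numpy()}
    )
    agg = sub.groupby(["row", "col"])["taxon"].nunique()
    for (r, c), n in agg.items():
        counts[r, c] = n
    return counts


def richness_grid(frame: pd.DataFrame, grid: GridSpec) -> RichnessGrid:
    return RichnessGrid(
        grid=grid,
        species=richness_per_cell(frame, grid, "species"),
        genus=richness_per_cell(frame, grid, "genus"),
    )


def diversification_surface(richness: RichnessGrid) -> np.ndarray:
    """Species-per-genus ratio per cell; NaN (no-data) where no genus occurs."""
    species = np.asarray(richness.species, dtype=float)
    genus = np.asarray(richness.genus, dtype=float)
    if species.shape != genus.shape:
        raise InputError("species and genus layers are not co-registered")
    out = np.full(species.shape, np.nan)
    np.divide(species, genus, out=out, where=genus > 0)
    return out


@dataclass
class RangeSummary:
    """Per-species occupancy on an equal-area lattice."""

    species: str
    n_records: int
    n_cells: int
    aoo: float  # n_cells * cell area (km² on an equal-area km grid)


def area_of_occupancy(
    frame: pd.DataFrame, grid: GridSpec, species: str | None = None
) -> RangeSummary:
    """AOO of one species: cell area x number of distinct occupied cells.

    ``frame`` holds the georeferenced clean records of a single species
    (or pass ``species`` to subset).  Zero usable records is an error —
    an unknown range is not a range of zero.
    """
    if species is not None:
        frame = frame[frame["scientificName"] == species]
    names = frame["scientificName"].unique()
    if len(names) > 1:
        raise InputError(f"records of {len(names)} species passed to area_of_occupancy")
    if len(frame) == 0:
        raise InputError("area of occupancy is undefined for zero records")
    rows, cols, inside = assign_cells(
        frame["decimalLongitude"].to_numpy(float),
        frame["decimalLatitude"].to_numpy(float),
        grid,
    )
    if not inside.any():
        raise InputError("no record falls inside the grid extent")
    occupied = set(zip(rows[inside].tolist(), cols[inside].tolist()))
    return RangeSummary(
        species=str(names[0]) if len(names) else "",
        n_records=int(inside.sum()),
        n_cells=len(occupied),
        aoo=grid.cell_area * len(occupied),
    )


def range_summaries(frame: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """AOO table for every species in a cleaned occurrence frame."""
    rows = []
    for name, sub in frame.groupby("scientificName", sort=True):
        summary = area_of_occupancy(sub, grid)
        rows.append(
            {
                "species": name,
                "genus": sub["genus"].iloc[0],
                "n_records": summary.n_records,
                "n_cells": summary.n_cells,
                "aoo": summary.aoo,
            }
        )
    return pd.DataFrame(rows, columns=["species", "genus", "n_records", "n_cells", "aoo"])


def occupied_fraction(
    frame: pd.DataFrame, grid: GridSpec, land_mask: np.ndarray
) -> float:
    """Percentage of land cells holding at least one record.

    ``land_mask`` is a boolean layer on ``grid`` (row 0 at the southern
    origin).  Records on non-land cells are ignored.
    """
    land_mask = np.asarray(land_mask, dtype=bool)
    if land_mask.shape != grid.shape():
        raise InputError("land mask is not co-registered with the grid")
    n_land = int(land_mask.sum())
    if n_land == 0:
        raise InputError("empty land mask")
    if len(frame) == 0:
        return 0.0
    rows, cols, inside = assign_cells(
        frame["decimalLongitude"].to_numpy(float),
        frame["decimalLatitude"].to_numpy(float),
        grid,
    )
    occ = np.zeros(grid.shape(), dtype=bool)
    occ[rows[inside], cols[inside]] = True
    return 100.0 * float((occ & land_mask).sum()) / n_land


# ---------------------------------------------------------------------------
# export helpers
# ---------------------------------------------------------------------------

def layer_to_raster(layer: np.ndarray, grid: GridSpec, nodata: float = -9999.0) -> Raster:
    """Grid layer (row 0 south) as a Raster (row 0 north) for ASCII export."""
    data = np.asarray(layer, dtype=float)[::-1].copy()
    data[np.isnan(data)] = nodata
    return Raster(data, xll=grid.x0, yll=grid.y0, cellsize=grid.dx, nodata=nodata)


def layer_to_long_csv(layer: np.ndarray, path) -> None:
    """Write a layer as long-format CSV with columns row, col, value."""
    layer = np.asarray(layer)
    rows, cols = np.nonzero(np.ones(layer.shape, dtype=bool))
    pd.DataFrame(
        {"row": rows, "col": cols, "value": layer[rows, cols]}
    ).to_csv(path, index=False)
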