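"""Overlay analyses: reserves, biomes, and climate space.

All operations take a cleaned occurrence DataFrame (the column layout of
the occurrence CSV) plus the relevant spatial layer and return plain
pandas/numpy results.  Boundary conventions: a record on a reserve
boundary counts as inside; climate and biome lookups are containing-cell
with no interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep
from shapely.strtree import STRtree

from .errors import InputError
from .rasters import Raster

logger = logging.getLogger(__name__)

PROTECTION_CATEGORIES = ("outside_only", "inside_only", "both")


def point_in_polygons(
    frame: pd.DataFrame, polygons: list[tuple[str, object]]
) -> tuple[np.ndarray, dict[str, set[str]]]:
    """Which records fall inside any polygon; which species touch each one.

    Returns ``(inside, per_polygon_species)`` where ``inside`` is a boolean
    per record (boundary points count as inside) and the dict maps polygon
    name -> set of species with at least one record intersecting it.
    Overlapping polygons each receive the species.
    """
    lon = frame["decimalLongitude"].to_numpy(float)
    lat = frame["decimalLatitude"].to_numpy(float)
    names = frame["scientificName"].to_numpy()
    inside = np.zeros(len(frame), dtype=bool)
    per_polygon: dict[str, set[str]] = {name: set() for name, _ in polygons}
    if not polygons or len(frame) == 0:
        return inside, per_polygon

    geoms = [geom for _, geom in polygons]
    poly_names = [name for name, _ in polygons]
    tree = STRtree(geoms)
    points = [Point(x, y) for x, y in zip(lon, lat)]
    # STRtree query gives candidate pairs; confirm with intersects (covers
    # boundary points, unlike contains)
    pt_idx, poly_idx = tree.query(points, predicate="intersects")
    for pi, gi in zip(pt_idx.tolist(), poly_idx.tolist()):
        inside[pi] = True
        per_polygon[poly_names[gi]].add(str(names[pi]))
    return inside, per_polygon


@dataclass
class ProtectionSummary:
    counts: dict[str, int]           # category -> species count
    percentages: dict[str, float]    # category -> % of classified species
    n_species: int
    n_polygons_occupied: int
    unclassified: list[str]          # species with no resolvable record


def category_percentage(count: int, total: int) -> float:
    """Share of species in a protection category, in percent (1 decimal scale)."""
    if total <= 0:
        raise InputError("total species count must be positive")
    return 100.0 * count / total


def protection_classification(
    frame: pd.DataFrame, polygons: list[tuple[str, object]]
) -> tuple[pd.DataFrame, ProtectionSummary]:
    """Classify every species as outside-only / inside-only / both.

    The three categories partition the classified species; species with no
    georeferenced record are listed separately and excluded from the
    percentages.  Also reports how many reserves hold at least one species
    (overlapping reserves are counted independently).
    """
    geo = frame[
        frame["decimalLatitude"].notna() & frame["decimalLongitude"].notna()
    ].reset_index(drop=True)
    unclassified = sorted(
        set(frame["scientificName"]) - set(geo["scientificName"])
    )
    inside, per_polygon = point_in_polygons(geo, polygons)

    rows = []
    for name, grp_idx in geo.groupby("scientificName", sort=True).groups.items():
        flags = inside[np.asarray(grp_idx)]
        any_in, any_out = bool(flags.any()), bool((~flags).any())
        category = "both" if (any_in and any_out) else (
            "inside_only" if any_in else "outside_only"
        )
        rows.append(
            {
                "species": name,
                "category": category,
                "n_records": len(flags),
                "n_records_inside": int(flags.sum()),
            }
        )
    table = pd.DataFrame(
        rows, columns=["species", "category", "n_records", "n_records_inside"]
    )
    counts = {cat: int((table["category"] == cat).sum()) for cat in PROTECTION_CATEGORIES}
    total = len(table)
    summary = ProtectionSummary(
        counts=counts,
        percentages={
            cat: category_percentage(n, total) if total else 0.0
            for cat, n in counts.items()
        },
        n_species=total,
        n_polygons_occupied=sum(1 for s in per_polygon.values() if s),
        unclassified=unclassified,
    )
    return table, summary


def biome_tally(
    frame: pd.DataFrame, biome_raster: Raster, labels: list[str]
) -> pd.DataFrame:
    """Distinct species and genus counts per biome.

    A species spanning several biomes is counted once in each.  Records on
    no-data cells (or outside the raster) are excluded with a logged count.
    """
    codes = biome_raster.value_at(
        frame["decimalLongitude"].to_numpy(float),
        frame["decimalLatitude"].to_numpy(float),
    )
    valid = ~np.isclose(codes, biome_raster.nodata)
    n_dropped = int(len(frame) - valid.sum())
    if n_dropped:
        logger.info("%d records fall on no-data biome cells and are excluded", n_dropped)
    sub = frame.loc[valid, ["scientificName", "genus"]].copy()
    sub["biome"] = [labels[int(c)] for c in codes[valid]]
    agg = sub.groupby("biome").agg(
        n_species=("scientificName", "nunique"), n_genera=("genus", "nunique")
    )
    out = agg.reindex(labels, fill_value=0).reset_index(names="biome")
    return out


def extract_climate(
    frame: pd.DataFrame, mat_raster: Raster, ap_raster: Raster
) -> pd.DataFrame:
    """Containing-cell MAT and AP for every record (no interpolation).

    Records on no-data cells or outside the rasters come back with
    ``valid=False`` and NaN climate values.
    """
    if not mat_raster.is_aligned_with(ap_raster):
        raise InputError("MAT and AP rasters are not co-registered")
    lon = frame["decimalLongitude"].to_numpy(float)
    lat = frame["decimalLatitude"].to_numpy(float)
    georef = ~(np.isnan(lon) | np.isnan(lat))
    mat = np.full(len(frame), np.nan)
    ap = np.full(len(frame), np.nan)
    if georef.any():
        mat[georef] = mat_raster.value_at(lon[georef], lat[georef])
        ap[georef] = ap_raster.value_at(lon[georef], lat[georef])
    valid = (
        georef
        & ~np.isclose(mat, mat_raster.nodata)
        & ~np.isclose(ap, ap_raster.nodata)
        & ~np.isnan(mat)
        & ~np.isnan(ap)
    )
    n_invalid = int(len(frame) - valid.sum())
    if n_invalid:
        logger.info("%d records failed climate extraction", n_invalid)
    out = pd.DataFrame(
        {
            "record_id": frame["record_id"].to_numpy(),
            "scientificName": frame["scientificName"].to_numpy(),
            "genus": frame["genus"].to_numpy(),
            "mat": np.where(valid, mat, np.nan),
            "ap": np.where(valid, ap, np.nan),
            "valid": valid,
        }
    )
    return out


def realized_vs_available(
    frame: pd.DataFrame, mat_raster: Raster, ap_raster: Raster
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occupied vs available climate space as (MAT, AP) point sets.

    ``available`` holds one point per land cell; ``realized`` one point
    per record with a valid climate sample.  Plotted against each other
    these show the climate-space void structure (e.g. absence from
    hot-and-dry conditions).
    """
    if not mat_raster.is_aligned_with(ap_raster):
        raise InputError("MAT and AP rasters are not co-registered")
    land = mat_raster.mask & ap_raster.mask
    available = pd.DataFrame(
        {"mat": mat_raster.data[land], "ap": ap_raster.data[land]}
    )
    samples = extract_climate(frame, mat_raster, ap_raster)
    realized = samples.loc[samples["valid"], ["mat", "ap"]].reset_index(drop=True)
    return realized, available
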