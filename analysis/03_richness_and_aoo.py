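"""Richness maps, the species-per-genus surface, and areas of occupancy.

Grids the cleaned records at 0.5° for species and genus richness, derives
the per-cell species/genus diversification ratio, measures each species'
area of occupancy on a 10 km equal-area lattice, and reports how much of
the landmass holds at least one record.
"""

import argparse
from pathlib import Path

import numpy as np

from orchidatlas.cleaning import read_occurrences, records_to_frame
from orchidatlas.rasters import read_ascii_grid, write_ascii_grid
from orchidatlas.spatial import (
    build_grid,
    layer_to_raster,
    occupied_fraction,
    range_summaries,
    richness_grid,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("scratch/study_system"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--richness-cell-deg", type=float, default=0.5)
    parser.add_argument("--aoo-cell-km", type=float, default=10.0)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    frame = records_to_frame(read_occurrences(args.datadir / "occurrences_clean.csv"))
    mat = read_ascii_grid(args.datadir / "mat.asc")
    extent = mat.extent

    deg_grid = build_grid(extent, args.richness_cell_deg)
    rich = richness_grid(frame, deg_grid)
    write_ascii_grid(layer_to_raster(rich.species, deg_grid),
                     args.outdir / "richness_species.asc")
    write_ascii_grid(layer_to_raster(rich.ratio, deg_grid),
                     args.outdir / "species_per_genus.asc")
    print(f"richness grid: {deg_grid.n_rows} x {deg_grid.n_cols} cells of "
          f"{args.richness_cell_deg}°")
    print(f"  max per-cell species richness: {rich.species.max()}")
    ratio = rich.ratio
    print(f"  max species-per-genus ratio: {np.nanmax(ratio):.2f}")

    # land mask on the richness lattice (every cell of the synthetic
    # continent is land)
    land = np.ones(deg_grid.shape(), dtype=bool)
    occ = occupied_fraction(frame, deg_grid, land)
    print(f"occupied landmass: {occ:.1f}% of {land.sum()} cells")

    aoo_grid = build_grid(extent, args.aoo_cell_km, "equal_area_km")
    ranges = range_summaries(frame, aoo_grid)
    ranges.to_csv(args.outdir / "range_summaries.csv", index=False)
    print(f"AOO over {len(ranges)} species: mean {ranges['aoo'].mean():.0f} km², "
          f"median {ranges['aoo'].median():.0f} km², "
          f"max {ranges['aoo'].max():.0f} km²")


if __name__ == "__main__":
    main()
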