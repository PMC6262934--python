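"""Grids, cell assignment, richness and AOO against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orchidatlas.errors import InputError
from orchidatlas.spatial import (
    area_of_occupancy,
    assign_cells,
    build_grid,
    cylindrical_equal_area,
    diversification_surface,
    identity_transform,
    occupied_fraction,
    range_summaries,
    richness_grid,
    richness_per_cell,
)

from conftest import make_frame


class TestBuildGrid:
    def test_exact_division(self):
        grid = build_grid((0, 0, 10, 10), 0.5)
        assert (grid.n_cols, grid.n_rows) == (20, 20)

    def test_ceiling_rule(self):
        grid = build_grid((0, 0, 10, 10), 0.6)
        assert (grid.n_cols, grid.n_rows) == (17, 17)

    def test_oversized_cell_gives_single_cell(self):
        grid = build_grid((0, 0, 2, 2), 5.0)
        assert (grid.n_cols, grid.n_rows) == (1, 1)

    def test_equal_area_mode_tiles_projected_extent(self):
        grid = build_grid((110, -45, 155, -10), 10.0, "equal_area_km")
        # ~45° of longitude at the mid-latitude parallel is ~3500-4000 km
        assert 300 < grid.n_cols < 450
        assert grid.cell_area == pytest.approx(100.0)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(InputError):
            build_grid((0, 0, 0, 10), 1.0)


class TestAssignCells:
    def test_origin_corner_is_cell_zero(self):
        grid = build_grid((0, 0, 10, 10), 1.0)
        rows, cols, inside = assign_cells([0.0], [0.0], grid)
        assert (rows[0], cols[0], inside[0]) == (0, 0, True)

    def test_interior_edge_goes_to_higher_cell(self):
        grid = build_grid((0, 0, 10, 10), 1.0)
        rows, cols, _ = assign_cells([3.0], [5.0], grid)
        assert (rows[0], cols[0]) == (5, 3)

    def test_extent_maximum_clamped_into_last_cell(self):
        grid = build_grid((0, 0, 10, 10), 1.0)
        rows, cols, inside = assign_cells([10.0], [10.0], grid)
        assert inside[0]
        assert (rows[0], cols[0]) == (9, 9)

    def test_matches_floor_division_oracle(self):
        rng = np.random.default_rng(42)
        grid = build_grid((2.0, -7.0, 13.0, 4.5), 0.37)
        x = rng.uniform(2.0, 13.0, size=10_000)
        y = rng.uniform(-7.0, 4.5, size=10_000)
        rows, cols, inside = assign_cells(x, y, grid)
        assert inside.all()
        exp_cols = np.floor((x - 2.0) / 0.37).astype(int)
        exp_rows = np.floor((y + 7.0) / 0.37).astype(int)
        np.testing.assert_array_equal(cols, np.minimum(exp_cols, grid.n_cols - 1))
        np.testing.assert_array_equal(rows, np.minimum(exp_rows, grid.n_rows - 1))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x0=st.floats(-50, 50),
        span=st.floats(0.5, 40),
        cell=st.floats(0.05, 5),
        fx=st.floats(0, 1),
        fy=st.floats(0, 1),
    )
    def test_every_extent_point_has_exactly_one_cell(self, x0, span, cell, fx, fy):
        grid = build_grid((x0, 0.0, x0 + span, span), cell)
        px, py = x0 + fx * span, fy * span
        rows, cols, inside = assign_cells([px], [py], grid)
        assert inside[0]
        assert 0 <= rows[0] < grid.n_rows and 0 <= cols[0] < grid.n_cols
        # the assigned cell actually contains the point (upper edges closed)
        assert grid.x0 + cols[0] * grid.dx <= px + 1e-9
        assert px <= grid.x0 + (cols[0] + 1) * grid.dx + 1e-9

    def test_equal_area_transform_preserves_area_element(self):
        # cylindrical equal-area: a 1°x1° patch at the standard parallel maps
        # to the same area as at any other latitude
        t = cylindrical_equal_area(-30.0)

        def patch_area(lat):
            x, y = t(np.array([0.0, 1.0]), np.array([lat, lat + 1.0]))
            return (x[1] - x[0]) * (y[1] - y[0]) / np.cos(np.radians(lat + 0.5))

        # areas agree after removing the cos(lat) ground-truth factor (small
        # secant error at 1° resolution)
        assert patch_area(-40.0) == pytest.approx(patch_area(-15.0), rel=0.01)


class TestRichness:
    def test_repeated_records_count_once(self):
        frame = make_frame([{"decimalLatitude": 0.5, "decimalLongitude": 0.5}] * 5)
        grid = build_grid((0, 0, 2, 2), 1.0)
        layer = richness_per_cell(frame, grid, "species")
        assert layer[0, 0] == 1
        assert layer.sum() == 1

    def test_congeneric_species_ratio(self):
        frame = make_frame(
            [
                {"scientificName": "Genus01 a"},
                {"scientificName": "Genus01 b"},
            ]
        )
        grid = build_grid((0, 0, 2, 2), 2.0)
        rich = richness_grid(frame, grid)
        assert rich.species[0, 0] == 2
        assert rich.genus[0, 0] == 1
        assert rich.ratio[0, 0] == 2.0

    def test_counts_match_set_based_oracle(self, clean_frame):
        grid = build_grid((0, 0, 20, 20), 0.5)
        rich = richness_grid(clean_frame, grid)
        rows, cols, inside = assign_cells(
            clean_frame["decimalLongitude"].to_numpy(),
            clean_frame["decimalLatitude"].to_numpy(),
            grid,
        )
        oracle_species = {}
        oracle_genus = {}
        for r, c, ok, name, genus in zip(
            rows, cols, inside, clean_frame["scientificName"], clean_frame["genus"]
        ):
            if not ok:
                continue
            oracle_species.setdefault((r, c), set()).add(name)
            oracle_genus.setdefault((r, c), set()).add(genus)
        for (r, c), names in oracle_species.items():
            assert rich.species[r, c] == len(names)
            assert rich.genus[r, c] == len(oracle_genus[(r, c)])
        assert rich.species.sum() == sum(map(len, oracle_species.values()))

    def test_distinctness_bounds(self, clean_frame):
        grid = build_grid((0, 0, 20, 20), 1.0)
        rich = richness_grid(clean_frame, grid)
        assert np.all(rich.genus <= rich.species)
        ratio = rich.ratio
        assert np.all(ratio[~np.isnan(ratio)] >= 1.0)

    def test_empty_input_all_zero(self):
        grid = build_grid((0, 0, 4, 4), 1.0)
        layer = richness_per_cell(make_frame([]), grid, "species")
        assert layer.sum() == 0


class TestDiversificationSurface:
    def test_division_and_nodata(self):
        grid = build_grid((0, 0, 2, 1), 1.0)
        from orchidatlas.spatial import RichnessGrid

        rich = RichnessGrid(
            grid=grid,
            species=np.array([[6, 0]]),
            genus=np.array([[2, 0]]),
        )
        surface = diversification_surface(rich)
        assert surface[0, 0] == 3.0
        assert np.isnan(surface[0, 1])  # empty cell is no-data, not 0


class TestAreaOfOccupancy:
    def grid(self):
        return build_grid(
            (0, 0, 100, 100), 10.0, "equal_area_km", transform=identity_transform
        )

    def test_single_record_minimum(self):
        frame = make_frame([{"decimalLatitude": 5.0, "decimalLongitude": 5.0}])
        assert area_of_occupancy(frame, self.grid()).aoo == 100.0

    def test_distinct_cell_counting(self):
        frame = make_frame(
            [
                {"decimalLatitude": 5.0, "decimalLongitude": 5.0},
                {"decimalLatitude": 6.0, "decimalLongitude": 6.0},  # same cell
                {"decimalLatitude": 55.0, "decimalLongitude": 5.0},
            ]
        )
        summary = area_of_occupancy(frame, self.grid())
        assert summary.n_cells == 2
        assert summary.aoo == 200.0

    def test_zero_records_is_an_error_not_zero(self):
        with pytest.raises(InputError):
            area_of_occupancy(make_frame([]), self.grid())

    def test_matches_distinct_cell_oracle(self):
        rng = np.random.default_rng(7)
        rows = [
            {"decimalLatitude": float(lat), "decimalLongitude": float(lon)}
            for lat, lon in zip(rng.uniform(0, 100, 500), rng.uniform(0, 100, 500))
        ]
        frame = make_frame(rows)
        grid = self.grid()
        summary = area_of_occupancy(frame, grid)
        oracle = {
            (int(r["decimalLatitude"] // 10), int(r["decimalLongitude"] // 10))
            for r in rows
        }
        assert summary.n_cells == len(oracle)
        assert summary.aoo == 100.0 * len(oracle)

    def test_duplication_invariance_and_monotonicity(self):
        frame = make_frame(
            [{"decimalLatitude": 5.0, "decimalLongitude": 5.0},
             {"decimalLatitude": 55.0, "decimalLongitude": 55.0}]
        )
        grid = self.grid()
        base = area_of_occupancy(frame, grid).aoo
        doubled = area_of_occupancy(
            pd.concat([frame, frame], ignore_index=True), grid
        ).aoo
        assert doubled == base
        extra = make_frame(
            [{"decimalLatitude": 95.0, "decimalLongitude": 95.0}]
        )
        grown = area_of_occupancy(
            pd.concat([frame, extra], ignore_index=True), grid
        ).aoo
        assert grown >= base


class TestOccupiedFraction:
    def test_saturation_and_empty(self):
        grid = build_grid((0, 0, 4, 4), 2.0)
        land = np.ones((2, 2), dtype=bool)
        full = make_frame(
            [
                {"decimalLatitude": y, "decimalLongitude": x}
                for x in (1.0, 3.0)
                for y in (1.0, 3.0)
            ]
        )
        assert occupied_fraction(full, grid, land) == 100.0
        assert occupied_fraction(make_frame([]), grid, land) == 0.0
        with pytest.raises(InputError):
            occupied_fraction(full, grid, np.zeros((2, 2), dtype=bool))

    def test_occupied_cells_subset_of_true_range_union(self, small_dataset, clean_frame):
        # on the raster lattice itself, occupied cells must be a subset of
        # the union of ledgered true-range cells, and approach it from below
        mat = small_dataset.mat
        grid = build_grid(mat.extent, mat.cellsize)
        rows, cols, inside = assign_cells(
            clean_frame["decimalLongitude"].to_numpy(),
            clean_frame["decimalLatitude"].to_numpy(),
            grid,
        )
        # grid rows count from the south; ledger cells from the north
        occupied = {
            (mat.n_rows - 1 - r, c) for r, c in zip(rows[inside], cols[inside])
        }
        union = small_dataset.ledger.true_range_union()
        assert occupied <= union
        frac = occupied_fraction(clean_frame, grid, np.ones(grid.shape(), bool))
        assert frac <= 100.0 * len(union) / (mat.n_rows * mat.n_cols) + 1e-9

    def test_monotone_in_record_set(self, clean_frame):
        grid = build_grid((0, 0, 20, 20), 1.0)
        land = np.ones(grid.shape(), dtype=bool)
        half = occupied_fraction(clean_frame.head(len(clean_frame) // 2), grid, land)
        full = occupied_fraction(clean_frame, grid, land)
        assert full >= half


def test_range_summaries_cover_every_species(clean_frame):
    grid = build_grid((0, 0, 20, 20), 0.5, "equal_area_km", transform=identity_transform)
    table = range_summaries(clean_frame, grid)
    assert set(table["species"]) == set(clean_frame["scientificName"])
    assert (table["n_cells"] <= table["n_records"]).all()
    assert (table["aoo"] == table["n_cells"] * grid.cell_area).all()
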