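"""Reserve overlays, biome tallies and climate extraction vs independent
point-in-polygon / group-by / index-arithmetic oracles."""

import numpy as np
import pytest
from shapely.geometry import box

from orchidatlas.errors import InputError
from orchidatlas.overlays import (
    biome_tally,
    category_percentage,
    extract_climate,
    point_in_polygons,
    protection_classification,
    realized_vs_available,
)
from orchidatlas.rasters import Raster

from conftest import make_frame


def ray_casting_inside(px, py, polygon) -> bool:
    """Independent crossing-number test (boundary resolved separately)."""
    coords = list(polygon.exterior.coords)
    inside = False
    for (x1, y1), (x2, y2) in zip(coords, coords[1:]):
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


class TestPointInPolygons:
    def test_interior_and_boundary_points_are_inside(self):
        poly = [("pa", box(0, 0, 2, 2))]
        frame = make_frame(
            [
                {"decimalLatitude": 1.0, "decimalLongitude": 1.0},   # center
                {"decimalLatitude": 2.0, "decimalLongitude": 1.0},   # edge
                {"decimalLatitude": 3.0, "decimalLongitude": 1.0},   # outside
            ]
        )
        inside, per_poly = point_in_polygons(frame, poly)
        assert inside.tolist() == [True, True, False]
        assert per_poly["pa"] == {"Genus01 species001"}

    def test_matches_ray_casting_oracle(self):
        rng = np.random.default_rng(31)
        polys = []
        for i in range(30):
            x0, y0 = rng.uniform(0, 8, size=2)
            w, h = rng.uniform(0.5, 3, size=2)
            polys.append((f"pa{i}", box(x0, y0, x0 + w, y0 + h)))
        xs = rng.uniform(0, 10, size=1000)
        ys = rng.uniform(0, 10, size=1000)
        frame = make_frame(
            [{"decimalLatitude": y, "decimalLongitude": x} for x, y in zip(xs, ys)]
        )
        inside, _ = point_in_polygons(frame, polys)
        # boundary hits have probability zero for random points, so the
        # crossing-number oracle is exact here
        for k in range(1000):
            expected = any(ray_casting_inside(xs[k], ys[k], p) for _, p in polys)
            assert inside[k] == expected

    def test_overlapping_polygons_each_receive_species(self):
        polys = [("a", box(0, 0, 2, 2)), ("b", box(1, 1, 3, 3))]
        frame = make_frame([{"decimalLatitude": 1.5, "decimalLongitude": 1.5}])
        _, per_poly = point_in_polygons(frame, polys)
        assert per_poly["a"] == per_poly["b"] == {"Genus01 species001"}


class TestProtectionClassification:
    def test_three_categories_partition_species(self):
        polys = [("pa", box(0, 0, 5, 5))]
        frame = make_frame(
            [
                {"scientificName": "A a", "decimalLatitude": 1.0},
                {"scientificName": "A a", "decimalLatitude": 8.0},  # both
                {"scientificName": "B b", "decimalLatitude": 2.0},  # inside only
                {"scientificName": "C c", "decimalLatitude": 9.0},  # outside only
            ]
        )
        table, summary = protection_classification(frame, polys)
        assert dict(zip(table["species"], table["category"])) == {
            "A a": "both", "B b": "inside_only", "C c": "outside_only",
        }
        assert sum(summary.counts.values()) == summary.n_species == 3
        assert summary.n_polygons_occupied == 1

    def test_full_extent_polygon_everything_inside_only(self, clean_frame):
        polys = [("all", box(-1, -1, 21, 21))]
        table, summary = protection_classification(clean_frame, polys)
        assert (table["category"] == "inside_only").all()
        assert summary.percentages["inside_only"] == 100.0

    def test_no_polygons_everything_outside_only(self, clean_frame):
        table, summary = protection_classification(clean_frame, [])
        assert (table["category"] == "outside_only").all()
        assert summary.n_polygons_occupied == 0

    def test_percentage_arithmetic(self):
        assert category_percentage(211, 1538) == pytest.approx(13.7, abs=0.05)
        assert category_percentage(124, 1538) == pytest.approx(8.1, abs=0.05)
        with pytest.raises(InputError):
            category_percentage(1, 0)

    def test_recovers_ledger_categories(self, small_dataset, clean_frame):
        table, _ = protection_classification(
            clean_frame, small_dataset.protected_areas
        )
        observed = dict(zip(table["species"], table["category"]))
        for name, sp in small_dataset.ledger.species.items():
            if sp.protection_category is not None:
                assert observed[name] == sp.protection_category


def _toy_rasters():
    # 2 x 2 cells over (0,0)-(2,2); row 0 is the northern row
    mat = Raster(np.array([[10.0, 20.0], [30.0, -9999.0]]), 0, 0, 1.0)
    ap = Raster(np.array([[100.0, 200.0], [300.0, -9999.0]]), 0, 0, 1.0)
    return mat, ap


class TestBiomeTally:
    def test_group_by_oracle(self, small_dataset, clean_frame):
        tallies = biome_tally(
            clean_frame, small_dataset.biomes, small_dataset.biome_labels
        )
        codes = small_dataset.biomes.value_at(
            clean_frame["decimalLongitude"].to_numpy(),
            clean_frame["decimalLatitude"].to_numpy(),
        )
        oracle: dict[str, set] = {}
        for code, name in zip(codes, clean_frame["scientificName"]):
            oracle.setdefault(small_dataset.biome_labels[int(code)], set()).add(name)
        for row in tallies.itertuples():
            assert row.n_species == len(oracle.get(row.biome, set()))
        # union of per-biome species sets = all species with resolvable biome
        assert set().union(*oracle.values()) == set(clean_frame["scientificName"])

    def test_concentration_and_multi_membership(self):
        biomes = Raster(np.array([[0.0, 1.0]]), 0, 0, 1.0)
        labels = ["left", "right"]
        frame = make_frame(
            [
                {"scientificName": "A a", "decimalLatitude": 0.5, "decimalLongitude": 0.5},
                {"scientificName": "A a", "decimalLatitude": 0.5, "decimalLongitude": 1.5},
                {"scientificName": "B b", "decimalLatitude": 0.5, "decimalLongitude": 0.5},
            ]
        )
        tallies = biome_tally(frame, biomes, labels).set_index("biome")
        assert tallies.loc["left", "n_species"] == 2
        assert tallies.loc["right", "n_species"] == 1  # A a counted in both


class TestExtractClimate:
    def test_containing_cell_lookup(self):
        mat, ap = _toy_rasters()
        frame = make_frame(
            [{"decimalLatitude": 1.5, "decimalLongitude": 0.5}]  # NW cell
        )
        out = extract_climate(frame, mat, ap)
        assert out.loc[0, "mat"] == 10.0
        assert out.loc[0, "ap"] == 100.0

    def test_nodata_cell_invalid(self):
        mat, ap = _toy_rasters()
        frame = make_frame(
            [{"decimalLatitude": 0.5, "decimalLongitude": 1.5},   # nodata cell
             {"decimalLatitude": 5.0, "decimalLongitude": 5.0}]   # outside
        )
        out = extract_climate(frame, mat, ap)
        assert not out["valid"].any()
        assert out["mat"].isna().all()

    def test_matches_index_arithmetic_oracle(self, small_dataset, clean_frame):
        mat = small_dataset.mat
        out = extract_climate(clean_frame, mat, small_dataset.ap)
        lon = clean_frame["decimalLongitude"].to_numpy()
        lat = clean_frame["decimalLatitude"].to_numpy()
        cols = np.floor((lon - mat.xll) / mat.cellsize).astype(int)
        rows = mat.n_rows - 1 - np.floor((lat - mat.yll) / mat.cellsize).astype(int)
        np.testing.assert_allclose(out["mat"], mat.data[rows, cols])

    def test_idempotent_and_order_independent(self, small_dataset, clean_frame):
        out1 = extract_climate(clean_frame, small_dataset.mat, small_dataset.ap)
        shuffled = clean_frame.sample(frac=1.0, random_state=0)
        out2 = extract_climate(shuffled, small_dataset.mat, small_dataset.ap)
        merged = out1.merge(out2, on="record_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["mat_a"], merged["mat_b"])


class TestRealizedVsAvailable:
    def test_saturation_equals_available_multiset(self):
        mat, ap = _toy_rasters()
        centers = [(1.5, 0.5), (1.5, 1.5), (0.5, 0.5)]  # every land cell
        frame = make_frame(
            [{"decimalLatitude": y, "decimalLongitude": x} for y, x in centers]
        )
        realized, available = realized_vs_available(frame, mat, ap)
        assert sorted(map(tuple, realized.to_numpy().tolist())) == sorted(
            map(tuple, available.to_numpy().tolist())
        )

    def test_no_records_empty_realized(self):
        mat, ap = _toy_rasters()
        realized, available = realized_vs_available(make_frame([]), mat, ap)
        assert len(realized) == 0
        assert len(available) == 3  # nodata cell excluded

    def test_hot_dry_void(self, small_dataset, clean_frame):
        cfg = small_dataset.config
        realized, available = realized_vs_available(
            clean_frame, small_dataset.mat, small_dataset.ap
        )
        void_r = (realized["mat"] >= cfg.hot_dry_mat_min) & (
            realized["ap"] < cfg.hot_dry_ap_max
        )
        void_a = (available["mat"] >= cfg.hot_dry_mat_min) & (
            available["ap"] < cfg.hot_dry_ap_max
        )
        assert void_r.sum() == 0
        assert void_a.sum() > 0  # the climate exists, the species avoid it
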