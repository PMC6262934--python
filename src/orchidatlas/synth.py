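"""Synthetic study system with known ground truth.

Emulates the inputs of a continental herbarium analysis — an occurrence
table in Darwin-Core-style columns, co-registered climate surfaces (mean
annual temperature, annual precipitation), a six-biome climate
classification, and a reserve polygon network — for a rectangular synthetic
"continent" in decimal degrees.  Every species has a known climate niche
box, a known set of occupied raster cells, a known record count, and a
known protection category, all written to a truth ledger so that each
downstream stage of the pipeline can be tested against construction-time
truth rather than against itself.

Contamination mirroring the seven occurrence-cleaning rules (genus-only
names, wrong country, missing coordinates, exact duplicates, cultivated,
hybrids, naturalized) is injected at configurable per-rule rates and
ledgered with exact expected removal counts.

All randomness flows from ``SyntheticConfig.seed``; each generation stage
derives its own independent stream so that, e.g., changing the number of
protected areas does not perturb the species pool.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union
from shapely.prepared import prep

from .errors import ConfigError, InputError
from .rasters import Raster, write_ascii_grid

logger = logging.getLogger(__name__)

CLEANING_RULES = ("a", "b", "c", "d", "e", "f", "g")

#: Column layout of the occurrence CSV (Darwin-Core-flavoured).
OCCURRENCE_COLUMNS = [
    "record_id",
    "scientificName",
    "genus",
    "family",
    "decimalLatitude",
    "decimalLongitude",
    "country",
    "cultivated",
    "hybrid",
    "establishmentMeans",
]

# Stage constants mixed into the seed so each stage has its own stream.
_STAGE_CLIMATE = 101
_STAGE_POOL = 211
_STAGE_OCC = 307
_STAGE_PA = 401


@dataclass(frozen=True)
class BiomeRule:
    """Half-open box in (MAT, AP) climate space mapped to one biome label."""

    label: str
    mat_min: float = -np.inf
    mat_max: float = np.inf
    ap_min: float = -np.inf
    ap_max: float = np.inf

    def matches(self, mat, ap):
        mat = np.asarray(mat, dtype=float)
        ap = np.asarray(ap, dtype=float)
        return (
            (mat >= self.mat_min)
            & (mat < self.mat_max)
            & (ap >= self.ap_min)
            & (ap < self.ap_max)
        )


#: Six-biome partition of climate space (desert where hot and dry).
DEFAULT_BIOME_RULES = (
    BiomeRule("desert", mat_min=24.0, ap_max=300.0),
    BiomeRule("tropical", mat_min=24.0, ap_min=300.0, ap_max=1500.0),
    BiomeRule("equatorial", mat_min=24.0, ap_min=1500.0),
    BiomeRule("grassland", mat_min=16.0, mat_max=24.0, ap_max=400.0),
    BiomeRule("subtropical", mat_min=16.0, mat_max=24.0, ap_min=400.0),
    BiomeRule("temperate", mat_max=16.0),
)


def default_contamination_rates() -> dict[str, float]:
    """Per-rule contamination fractions of the clean record count.

    Chosen to resemble the messiness of a large aggregated herbarium
    export: missing coordinates and duplicates dominate; cultivated,
    hybrid and naturalized records are a few percent each.
    """
    return {
        "a": 0.02,   # identified to genus only
        "b": 0.005,  # collected in another country
        "c": 0.05,   # no georeference
        "d": 0.03,   # exact duplicate rows
        "e": 0.01,   # cultivated specimens
        "f": 0.01,   # hybrid combinations
        "g": 0.02,   # naturalized, not native
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic continent and species pool.

    Defaults describe the study conditions the pipeline is exercised
    under: a ~45°x35° continent, 20 genera of 5-60 species, 3-200 records
    per species (~30k rows), smooth opposing MAT/AP gradients with a hot,
    dry (desert) corner that orchid niches are excluded from, and the five
    most speciose genera carrying distinctly narrower rainfall niches.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (110.0, -45.0, 155.0, -10.0)
    raster_cellsize: float = 0.25

    # climate surfaces: MAT rises south->north, AP rises west->east
    mat_range: tuple[float, float] = (5.0, 30.0)
    ap_range: tuple[float, float] = (100.0, 2200.0)
    mat_noise_sd: float = 0.8
    ap_noise_sd: float = 40.0

    # species pool
    n_genera: int = 20
    species_per_genus: tuple[int, int] = (5, 60)       # uniform integers
    records_per_species: tuple[int, int] = (3, 200)    # log-uniform integers
    mat_width_range: tuple[float, float] = (2.0, 8.0)  # °C niche widths
    ap_width_range: tuple[float, float] = (400.0, 1000.0)  # mm niche widths
    narrow_ap_width_range: tuple[float, float] = (80.0, 200.0)
    n_narrow_ap_genera: int = 5  # most speciose genera get narrow AP niches

    # realized-niche void: niches avoid hot-and-dry climate space
    exclude_hot_dry: bool = True
    hot_dry_mat_min: float = 24.0
    hot_dry_ap_max: float = 300.0

    contamination_rates: dict[str, float] = field(
        default_factory=default_contamination_rates
    )

    n_protected_areas: int = 60
    protected_fraction_target: float = 0.15

    country: str = "Australia"
    family: str = "Orchidaceae"

    def __post_init__(self) -> None:
        min_x, min_y, max_x, max_y = self.extent
        if not (max_x > min_x and max_y > min_y):
            raise ConfigError(f"degenerate extent {self.extent}")
        for rule, rate in self.contamination_rates.items():
            if rule not in CLEANING_RULES:
                raise ConfigError(f"unknown contamination rule {rule!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"contamination rate for {rule!r} not in [0,1]: {rate}")
        if not 0.0 <= self.protected_fraction_target <= 1.0:
            raise ConfigError(
                f"protected_fraction_target not in [0,1]: {self.protected_fraction_target}"
            )
        if self.n_genera < 2:
            raise ConfigError("need at least 2 genera")
        if self.n_protected_areas < 0:
            raise ConfigError("n_protected_areas must be >= 0")
        if self.species_per_genus[0] < 1 or self.records_per_species[0] < 1:
            raise ConfigError("species and record counts must be >= 1")
        n_cols = (max_x - min_x) / self.raster_cellsize
        n_rows = (max_y - min_y) / self.raster_cellsize
        if n_cols < 10 or n_rows < 10:
            raise ConfigError("raster resolution must give at least a 10 x 10 grid")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class SpeciesTruth:
    """Ground truth for one synthetic species."""

    name: str
    genus: str
    mat_center: float
    mat_width: float
    ap_center: float
    ap_width: float
    range_cells: list[tuple[int, int]]  # (row, col) into the climate raster
    n_clean_records: int = 0
    protection_category: str | None = None  # outside_only | inside_only | both


@dataclass
class TruthLedger:
    """Everything the generator knows that the pipeline must recover."""

    species: dict[str, SpeciesTruth] = field(default_factory=dict)
    expected_removals: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in CLEANING_RULES}
    )
    n_raw_records: int = 0
    n_clean_records: int = 0

    @property
    def genera(self) -> list[str]:
        return sorted({s.genus for s in self.species.values()})

    def species_per_genus(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sp in self.species.values():
            out[sp.genus] = out.get(sp.genus, 0) + 1
        return out

    def true_range_union(self) -> set[tuple[int, int]]:
        cells: set[tuple[int, int]] = set()
        for sp in self.species.values():
            cells.update(map(tuple, sp.range_cells))
        return cells

    def to_json(self, path: str | Path) -> None:
        payload = {
            "expected_removals": self.expected_removals,
            "n_raw_records": self.n_raw_records,
            "n_clean_records": self.n_clean_records,
            "species": {
                name: {
                    **{
                        k: v
                        for k, v in dataclasses.asdict(sp).items()
                        if k != "range_cells"
                    },
                    "range_cells": [list(c) for c in sp.range_cells],
                }
                for name, sp in self.species.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        payload = json.loads(Path(path).read_text())
        ledger = cls(
            expected_removals={
                k: int(v) for k, v in payload["expected_removals"].items()
            },
            n_raw_records=int(payload["n_raw_records"]),
            n_clean_records=int(payload["n_clean_records"]),
        )
        for name, d in payload["species"].items():
            d = dict(d)
            d["range_cells"] = [tuple(c) for c in d["range_cells"]]
            ledger.species[name] = SpeciesTruth(**d)
        return ledger


# ---------------------------------------------------------------------------
# climate surfaces
# ---------------------------------------------------------------------------

def generate_climate_surfaces(config: SyntheticConfig) -> tuple[Raster, Raster]:
    """Two co-registered climate rasters over the synthetic continent.

    MAT follows a linear south-to-north gradient, AP an independent
    west-to-east gradient, each plus i.i.d. Gaussian cell noise, so the
    low-AP/high-MAT (north-west) corner is hot and dry.  The gradient value
    at a cell is evaluated at the cell center.
    """
    min_x, min_y, max_x, max_y = config.extent
    cs = config.raster_cellsize
    n_cols = int(np.ceil((max_x - min_x) / cs - 1e-9))
    n_rows = int(np.ceil((max_y - min_y) / cs - 1e-9))

    rng = config.rng(_STAGE_CLIMATE)
    # fractional position of cell centers along each gradient axis
    fy = (np.arange(n_rows - 1, -1, -1)[:, None] + 0.5) / n_rows  # north at row 0
    fx = (np.arange(n_cols)[None, :] + 0.5) / n_cols

    mat_lo, mat_hi = config.mat_range
    ap_lo, ap_hi = config.ap_range
    mat = mat_lo + (mat_hi - mat_lo) * np.broadcast_to(fy, (n_rows, n_cols)).copy()
    ap = ap_lo + (ap_hi - ap_lo) * np.broadcast_to(fx, (n_rows, n_cols)).copy()
    if config.mat_noise_sd > 0:
        mat += rng.normal(0.0, config.mat_noise_sd, size=mat.shape)
    if config.ap_noise_sd > 0:
        ap += rng.normal(0.0, config.ap_noise_sd, size=ap.shape)
        np.clip(ap, 0.0, None, out=ap)

    mat_raster = Raster(mat, xll=min_x, yll=min_y, cellsize=cs)
    ap_raster = Raster(ap, xll=min_x, yll=min_y, cellsize=cs)
    return mat_raster, ap_raster


# ---------------------------------------------------------------------------
# biome map
# ---------------------------------------------------------------------------

def generate_biome_map(
    mat_raster: Raster,
    ap_raster: Raster,
    rules: tuple[BiomeRule, ...] = DEFAULT_BIOME_RULES,
) -> tuple[Raster, list[str]]:
    """Classify every land cell into exactly one biome.

    Returns a raster of integer label codes plus the ordered label list
    (code ``i`` means ``labels[i]``).  Raises :class:`ConfigError` if the
    rules overlap or leave any land cell unclassified.
    """
    if not mat_raster.is_aligned_with(ap_raster):
        raise InputError("MAT and AP rasters are not co-registered")
    if not rules:
        raise ConfigError("no biome rules given")

    land = mat_raster.mask & ap_raster.mask
    mat, ap = mat_raster.data, ap_raster.data
    match_count = np.zeros(mat.shape, dtype=int)
    codes = np.full(mat.shape, mat_raster.nodata)
    for i, rule in enumerate(rules):
        hit = rule.matches(mat, ap) & land
        match_count += hit
        codes[hit] = float(i)

    if np.any(match_count[land] == 0):
        raise ConfigError("biome rules leave part of climate space unclassified")
    if np.any(match_count[land] > 1):
        raise ConfigError("biome rules overlap in climate space")

    labels = [r.label for r in rules]
    return (
        Raster(codes, mat_raster.xll, mat_raster.yll, mat_raster.cellsize,
               nodata=mat_raster.nodata),
        labels,
    )


# ---------------------------------------------------------------------------
# species pool
# ---------------------------------------------------------------------------

def _species_name(genus: str, j: int) -> str:
    return f"{genus} species{j:03d}"


def generate_species_pool(
    config: SyntheticConfig, mat_raster: Raster, ap_raster: Raster
) -> TruthLedger:
    """Sample genera, species, niche boxes, and true range cells.

    Each species gets a niche center drawn inside the land climate range
    and a (MAT width, AP width) box; its true range is the set of land
    cells whose climate falls inside the box (minus the configured hot-dry
    exclusion zone).  The ``n_narrow_ap_genera`` most speciose genera draw
    AP widths from ``narrow_ap_width_range`` instead of ``ap_width_range``,
    giving the diversity-vs-breadth contrast a known sign.
    """
    if not mat_raster.is_aligned_with(ap_raster):
        raise InputError("MAT and AP rasters are not co-registered")

    rng = config.rng(_STAGE_POOL)
    land = mat_raster.mask & ap_raster.mask
    rows, cols = np.nonzero(land)
    mat_vals = mat_raster.data[rows, cols]
    ap_vals = ap_raster.data[rows, cols]
    usable = np.ones(mat_vals.shape, dtype=bool)
    if config.exclude_hot_dry:
        usable &= ~(
            (mat_vals >= config.hot_dry_mat_min) & (ap_vals < config.hot_dry_ap_max)
        )
    if not usable.any():
        raise InputError("hot-dry exclusion removes the entire continent")

    ledger = TruthLedger()
    lo, hi = config.species_per_genus
    genus_names = [f"Genus{i:02d}" for i in range(1, config.n_genera + 1)]
    n_species = rng.integers(lo, hi + 1, size=config.n_genera)

    # narrow-AP treatment goes to the most speciose genera (ties alphabetical)
    order = sorted(
        range(config.n_genera), key=lambda i: (-n_species[i], genus_names[i])
    )
    narrow = set(order[: config.n_narrow_ap_genera])

    u_mat = mat_vals[usable]
    u_ap = ap_vals[usable]
    mat_lo, mat_hi = float(u_mat.min()), float(u_mat.max())
    ap_lo, ap_hi = float(u_ap.min()), float(u_ap.max())

    for gi, genus in enumerate(genus_names):
        ap_w_range = (
            config.narrow_ap_width_range if gi in narrow else config.ap_width_range
        )
        for j in range(1, int(n_species[gi]) + 1):
            name = _species_name(genus, j)
            mat_w = float(rng.uniform(*config.mat_width_range))
            ap_w = float(rng.uniform(*ap_w_range))
            for attempt in range(20):
                mat_c = float(
                    rng.uniform(
                        min(mat_lo + mat_w / 2, mat_hi), max(mat_hi - mat_w / 2, mat_lo)
                    )
                )
                ap_c = float(
                    rng.uniform(
                        min(ap_lo + ap_w / 2, ap_hi), max(ap_hi - ap_w / 2, ap_lo)
                    )
                )
                in_box = (
                    usable
                    & (np.abs(mat_vals - mat_c) <= mat_w / 2)
                    & (np.abs(ap_vals - ap_c) <= ap_w / 2)
                )
                if in_box.any():
                    break
            else:
                raise InputError(
                    f"could not place a non-empty niche for {name} in 20 attempts"
                )
            if attempt:
                logger.debug("resampled niche center for %s %d times", name, attempt)
            cells = list(zip(rows[in_box].tolist(), cols[in_box].tolist()))
            ledger.species[name] = SpeciesTruth(
                name=name,
                genus=genus,
                mat_center=mat_c,
                mat_width=mat_w,
                ap_center=ap_c,
                ap_width=ap_w,
                range_cells=cells,
            )
    return ledger


# ---------------------------------------------------------------------------
# occurrences + contamination
# ---------------------------------------------------------------------------

def _jitter_in_cell(
    raster: Raster, row: int, col: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Near-uniform point inside cell (row, col); row counts from the north.

    Jitter is kept off the cell edges so that rounding coordinates to six
    decimals can never push a record into a neighbouring cell.
    """
    cs = raster.cellsize
    u = 0.001 + 0.998 * rng.random()
    v = 0.001 + 0.998 * rng.random()
    x = raster.xll + (col + u) * cs
    south_row = raster.n_rows - 1 - row
    y = raster.yll + (south_row + v) * cs
    return round(float(y), 6), round(float(x), 6)  # (lat, lon)


def _n_records(config: SyntheticConfig, rng: np.random.Generator) -> int:
    lo, hi = config.records_per_species
    if lo == hi:
        return lo
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def generate_occurrences(
    ledger: TruthLedger, config: SyntheticConfig, mat_raster: Raster
) -> pd.DataFrame:
    """Raw occurrence table: clean records plus ledgered contamination.

    Clean records are drawn uniformly (with replacement) from each
    species' true range cells and jittered uniformly within the cell.
    Contaminated rows are then appended, each constructed to trigger
    exactly one cleaning rule, at ``round(rate * n_clean)`` rows per rule;
    the ledger's ``expected_removals`` records these counts and the final
    table order is a seeded permutation.  Updates ``ledger`` in place.
    """
    rng = config.rng(_STAGE_OCC)
    rows: list[dict] = []
    rid = 0

    def base_row(sp: SpeciesTruth, lat: float, lon: float) -> dict:
        nonlocal rid
        rid += 1
        return {
            "record_id": f"syn{rid:06d}",
            "scientificName": sp.name,
            "genus": sp.genus,
            "family": config.family,
            "decimalLatitude": lat,
            "decimalLongitude": lon,
            "country": config.country,
            "cultivated": 0,
            "hybrid": 0,
            "establishmentMeans": "native",
        }

    species = list(ledger.species.values())
    for sp in species:
        n = _n_records(config, rng)
        cells = sp.range_cells
        picks = rng.integers(0, len(cells), size=n)
        for k in picks:
            lat, lon = _jitter_in_cell(mat_raster, *cells[k], rng)
            rows.append(base_row(sp, lat, lon))
        sp.n_clean_records = n

    n_clean = len(rows)
    ledger.n_clean_records = n_clean
    ledger.expected_removals = {r: 0 for r in CLEANING_RULES}

    def random_species() -> SpeciesTruth:
        return species[int(rng.integers(0, len(species)))]

    def fresh_coords(sp: SpeciesTruth) -> tuple[float, float]:
        cell = sp.range_cells[int(rng.integers(0, len(sp.range_cells)))]
        return _jitter_in_cell(mat_raster, *cell, rng)

    contaminated: list[dict] = []
    for rule in CLEANING_RULES:
        rate = config.contamination_rates.get(rule, 0.0)
        n_inject = int(round(rate * n_clean))
        if rule == "d" and n_inject > n_clean:
            raise ConfigError("duplicate rate implies more copies than base rows")
        for _ in range(n_inject):
            sp = random_species()
            if rule == "d":
                # exact string-level copy of an existing clean row
                contaminated.append(dict(rows[int(rng.integers(0, n_clean))]))
                continue
            lat, lon = fresh_coords(sp)
            row = base_row(sp, lat, lon)
            if rule == "a":
                row["scientificName"] = f"{sp.genus} sp."
            elif rule == "b":
                row["country"] = "New Zealand"
            elif rule == "c":
                row["decimalLatitude"] = np.nan
                row["decimalLongitude"] = np.nan
            elif rule == "e":
                row["cultivated"] = 1
            elif rule == "f":
                epithet = sp.name.split(" ", 1)[1]
                row["scientificName"] = f"{sp.genus} {epithet} × hybrida"
                row["hybrid"] = 1
            elif rule == "g":
                row["establishmentMeans"] = "naturalized"
            contaminated.append(row)
        ledger.expected_removals[rule] = n_inject

    ledger.n_raw_records = n_clean + len(contaminated)
    table = pd.DataFrame(rows + contaminated, columns=OCCURRENCE_COLUMNS)
    perm = rng.permutation(len(table))
    return table.iloc[perm].reset_index(drop=True)


# ---------------------------------------------------------------------------
# protected areas
# ---------------------------------------------------------------------------

def generate_protected_areas(config: SyntheticConfig) -> list[tuple[str, object]]:
    """Random rectangular reserves covering ~``protected_fraction_target``.

    Rectangle areas vary log-normally around an equal share of the target;
    after one Monte-Carlo-free measurement of the union area (shapely),
    all rectangles are rescaled about their centers once so that the
    covered fraction lands near the target despite overlaps.  Returns
    ``[(name, shapely Polygon), ...]``.
    """
    n = config.n_protected_areas
    if n == 0:
        return []
    min_x, min_y, max_x, max_y = config.extent
    extent_area = (max_x - min_x) * (max_y - min_y)
    target_area = config.protected_fraction_target * extent_area
    if target_area == 0:
        return []

    rng = config.rng(_STAGE_PA)
    areas = (target_area / n) * rng.lognormal(0.0, 0.4, size=n)
    ratios = rng.uniform(0.5, 2.0, size=n)
    widths = np.sqrt(areas * ratios)
    heights = areas / widths
    cx = rng.uniform(min_x, max_x, size=n)
    cy = rng.uniform(min_y, max_y, size=n)

    def build(scale: float) -> list:
        polys = []
        for i in range(n):
            w, h = widths[i] * scale, heights[i] * scale
            x0 = np.clip(cx[i] - w / 2, min_x, max_x - min(w, max_x - min_x))
            y0 = np.clip(cy[i] - h / 2, min_y, max_y - min(h, max_y - min_y))
            polys.append(
                box(x0, y0, min(x0 + w, max_x), min(y0 + h, max_y))
            )
        return polys

    polys = build(1.0)
    union_area = unary_union(polys).area
    if union_area > 0:
        polys = build(float(np.sqrt(target_area / union_area)))
    return [(f"PA_{i + 1:03d}", p) for i, p in enumerate(polys)]


def ledger_protection_categories(
    ledger: TruthLedger,
    occurrences: pd.DataFrame,
    polygons: list[tuple[str, object]],
    target_country: str = "Australia",
) -> None:
    """Fill each species' true protection category from its clean rows.

    "Clean" here means the generator's own uncontaminated rows (native,
    correct country, georeferenced, species-level names).  Boundary points
    count as inside, matching the overlay stage's convention.
    """
    from .cleaning import apply_filters, frame_to_records

    clean, _ = apply_filters(frame_to_records(occurrences), target_country)
    prepared = [prep(p) for _, p in polygons]
    by_species: dict[str, list[tuple[float, float]]] = {}
    for rec in clean:
        by_species.setdefault(rec.scientific_name, []).append(
            (rec.longitude, rec.latitude)
        )
    from shapely.geometry import Point

    for name, sp in ledger.species.items():
        pts = by_species.get(name, [])
        inside = outside = False
        for lon, lat in pts:
            p = Point(lon, lat)
            if any(pp.intersects(p) for pp in prepared):
                inside = True
            else:
                outside = True
        if inside and outside:
            sp.protection_category = "both"
        elif inside:
            sp.protection_category = "inside_only"
        elif outside:
            sp.protection_category = "outside_only"
        else:
            sp.protection_category = None


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    occurrences: pd.DataFrame
    mat: Raster
    ap: Raster
    biomes: Raster
    biome_labels: list[str]
    protected_areas: list[tuple[str, object]]
    ledger: TruthLedger


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run every generation stage in order and cross-link the truth."""
    mat, ap = generate_climate_surfaces(config)
    biomes, labels = generate_biome_map(mat, ap)
    ledger = generate_species_pool(config, mat, ap)
    occurrences = generate_occurrences(ledger, config, mat)
    pas = generate_protected_areas(config)
    ledger_protection_categories(ledger, occurrences, pas, config.country)
    return SyntheticDataset(config, occurrences, mat, ap, biomes, labels, pas, ledger)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact in its exchange format; returns the path map."""
    from .cleaning import write_occurrences, frame_to_records
    from .vector import write_protected_areas

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": outdir / "occurrences.csv",
        "mat": outdir / "mat.asc",
        "ap": outdir / "ap.asc",
        "biomes": outdir / "biomes.asc",
        "biome_labels": outdir / "biome_labels.json",
        "protected_areas": outdir / "protected_areas.geojson",
        "truth": outdir / "truth.json",
    }
    write_occurrences(frame_to_records(ds.occurrences), paths["occurrences"])
    write_ascii_grid(ds.mat, paths["mat"])
    write_ascii_grid(ds.ap, paths["ap"])
    write_ascii_grid(ds.biomes, paths["biomes"], fmt="%d")
    paths["biome_labels"].write_text(
        json.dumps({str(i): lab for i, lab in enumerate(ds.biome_labels)})
    )
    write_protected_areas(ds.protected_areas, paths["protected_areas"])
    ds.ledger.to_json(paths["truth"])
    return paths
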