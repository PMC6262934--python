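# Methods

This note documents the models, conventions and numerical choices behind
`orchidatlas`, and what the synthetic study system does and does not
establish about real herbarium data.

## The analysis model

The pipeline treats a herbarium export as a set of vouchered point
occurrences `(species, genus, family, lat, lon, provenance flags)` and
derives four families of quantities:

- **Occupancy.** On a cell lattice, a taxon occupies a cell if at least
  one of its records falls there; richness is the count of distinct taxa
  per cell, never record counts. Area of occupancy (AOO) for a species is
  `cell area × distinct occupied cells` on an equal-area lattice, the
  standard grid-based range-size metric; zero records give an error, not
  an AOO of 0, because an unsampled range is unknown rather than empty.
- **Coverage.** A species is protected-area "inside" if any record
  intersects any reserve polygon (boundary inclusive — conservative for
  gap analysis, since it never declares a boundary population
  unprotected). The three categories outside-only / inside-only / both
  partition the classified species.
- **Climate niche.** MAT and AP are read at each record by containing-cell
  lookup with no interpolation (deterministic, oracle-checkable, and the
  convention of standard occurrence workflows); niche breadth is the
  realized `max − min` per species. Breadth is therefore a *sample* range:
  it can only grow with more records and is bounded above by the species'
  true climatic tolerance.
- **Comparative statistics.** All tests are classical: simple least-squares
  regression with `F = (n−2)R²/(1−R²)` on (1, n−2) df; fixed-effects
  one-way ANOVA; Tukey-Kramer studentized-range comparisons for unequal
  group sizes. Log transforms are base 10 throughout and α = 0.05, with no
  multiple-testing correction beyond Tukey. Per-taxon collecting effort is
  `log₁₀(records / species)`.

## Grid and geometry conventions

- Cells are half-open `[edge, edge + size)`, lower-edge inclusive, so every
  point maps to exactly one cell; the extent's top/right boundary closes
  the final row/column so the extent tiles exactly.
- Cell counts are the ceiling of span/size; a cell larger than the extent
  degrades to a single-cell grid with a warning rather than an error.
- Two lattice modes exist because the two analysis grids have different
  needs: richness maps use plain geographic-degree cells (0.5° default),
  while AOO uses 10 km cells on coordinates pushed through an equal-area
  transform first. The default transform is a cylindrical equal-area
  mapping about the extent's mid-latitude (configurable standard
  parallel); synthetic-data tests use an identity "flat" transform so
  every spatial result stays analytically checkable. A degree lattice is
  *not* equal-area; exposing both modes makes that distinction explicit
  instead of hiding it in a projection default.
- Out-of-extent records are excluded with a logged count, not an error —
  tolerant handling appropriate to messy aggregated collections data.

## Cleaning semantics

Rules (a, b, c, e, f, g) are per-record predicates. Duplicates (d) —
nonunique (species name, latitude, longitude) — are detected among
records that no predicate flags, keeping the first row of each group.
Defining rule (d) this way makes the retained set provably independent of
the order rules are applied in; the configurable `rule_order` only
decides which rule a multiply-flagged row is *attributed* to in the
report. (A literal sequential implementation would not have this
property: a kept duplicate-representative could later be removed by
another rule while its discarded copy was otherwise clean.)

Coordinates in the duplicate key are compared as exact canonical decimal
strings with no rounding tolerance, since the duplicate definition used
in collections work states none. Species-level names are those whose
epithet token is `sp`/`sp.` or that consist of a single token; hybrids
are flagged records or names carrying `×` or ` x ` between epithets.

## The synthetic study system

`SyntheticConfig` defaults define the study conditions: a 45° × 35°
rectangular continent at 0.25° climate resolution; MAT rising south→north
(5–30 °C) and AP rising west→east (100–2200 mm), each with i.i.d.
Gaussian cell noise (0.8 °C, 40 mm), so the north-west corner is hot and
dry; a six-biome box partition of climate space with a desert label where
MAT ≥ 24 °C and AP < 300 mm; 20 genera of 5–60 species; 3–200 records per
species (log-uniform, ~30k rows total — sized so the full pipeline and
its seed sweeps run in minutes); contamination rates of 2/0.5/5/3/1/1/2 %
for rules (a)–(g), resembling a large aggregated export where missing
coordinates and duplicates dominate; 60 rectangular reserves targeting
15 % coverage; and narrow rainfall niche widths (80–200 mm vs
400–1000 mm) for the five most speciose genera, giving the
diversity-vs-breadth contrast a known sign.

Each species' niche is a box in (MAT, AP) space; its true range is the
set of land cells whose climate falls in the box, excluding the
configured hot-dry zone, so the realized climate space has a built-in
void. Clean records are drawn uniformly with replacement from true-range
cells and jittered uniformly within the cell (jitter is kept 0.1 % off
cell edges so six-decimal coordinate rounding can never cross a cell
boundary). Every contaminated row is constructed to trigger exactly one
rule, and the ledger records the exact injected count per rule, so
cleaning recovery is tested as *equality*, not approximation. All
randomness flows from one seed, with an independent stream per generation
stage.

What the generator does **not** emulate: real coastline and landmass
shape, spatially autocorrelated collecting bias (roads, herbaria,
population centres), taxonomic name churn, coordinate-precision
truncation, or climate surfaces with realistic covariance structure.
Passing tests therefore show that the *pipeline arithmetic* is correct
and that the statistical machinery is calibrated under known truth — not
that any particular real-world dataset is clean or that its niche
estimates are unbiased.

One visible consequence of the uniform-sampling model: with 10 km AOO
cells finer than the 0.25° sampling cells, nearly every record lands in
its own AOO cell, so the records-vs-range regression is almost perfectly
log-log linear with slope 1 at default scale. Real collections, with
revisited localities, sit well below that ceiling.

## Calibration and power sweeps

The central contrast — top-5 most speciose genera vs pooled remainder,
one-way ANOVA on log₁₀ niche breadth (species with breadth 0 excluded,
since log 0 is undefined; their count is logged) — is checked two ways on
a reduced continent (30° × 30° at 1°, 12 genera × 4–10 species × 8–25
records, ~15 ms per replicate):

- **Type-I error:** with no configured effect, the rejection rate at
  α = 0.05 over 1,000 seeds should sit at the nominal 5 % (accepted
  band 3–7 %; measured ≈ 5 % across seeds).
- **Power and sign:** with the narrow-rainfall configuration, the
  contrast should reject in ≥ 95 % of 100 seeds and the genus summaries
  should place the speciose genera's mean AP breadth below the pooled
  remainder's.

## Numerical choices and degenerate inputs

- Regression with zero x-variance, log of a non-positive value, ANOVA
  with fewer than two groups (or no group of size ≥ 2), AOO of zero
  records, an empty land mask, and overlapping or incomplete biome rules
  are all errors, raised with the offending input named.
- All-identical ANOVA data yields F = 0, p = 1 (not NaN); an exact-fit
  regression yields R² = 1 with p reported as 0.
- Tukey groups of size 1 are excluded with a warning; a two-group Tukey
  reproduces the ANOVA p (and the squared pooled-t), which the tests
  assert as an internal consistency identity.
- Diversity ties at the top-k boundary break alphabetically,
  deterministically. The pooled "remaining genera" group aggregates
  species-level values, not genus means, and its SE is the species-level
  sample SD over √n.
- The family-level effort contrast and the continent density contrast
  are implemented literally as two-group ANOVAs in which the focal taxon
  contributes a single value; the singleton layout is flagged in the
  result note rather than silently reshaped.
- Reserve generation rescales all rectangles once, about their centres,
  by `√(target area / measured union area)` to hit the coverage target
  despite overlaps; coverage is then within ~20 % relative of the target.

## Known limitations

- The equal-area transform is a single cylindrical equal-area formula,
  adequate for continental extents but not a substitute for a projection
  library when datum-accurate areas matter.
- Niche breadth as realized range is sensitive to sample size and
  outliers by construction; no kernel or hypervolume estimators are
  provided.
- Protection classification is binary per record; reserve category
  weighting and partial-range coverage fractions are out of scope.
- A record inside two overlapping reserves counts toward each reserve's
  occupancy tally independently.
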