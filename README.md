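# orchidatlas

A reproducible pipeline for continental-scale analyses of herbarium
occurrence records, built around the questions a collections-based study
of a hyperdiverse plant family (here, orchids) asks: where do the species
occur, how large are their ranges, how well does the reserve network
cover them, which biomes and climates do they occupy, and do the most
diverse genera differ in range size or climate niche breadth?

It is aimed at biodiversity informaticians and macroecologists who work
from point records (Darwin-Core-style CSV exports), gridded climate
surfaces, and reserve polygons — and who want every step of that workflow
to be testable against known ground truth.

## What it computes

1. **Record cleaning.** Seven auditable removal rules: (a) genus-only
   names, (b) wrong country, (c) no georeference, (d) duplicates
   (nonunique species + latitude + longitude), (e) cultivated,
   (f) hybrids, (g) naturalized. The retained set is invariant to rule
   order; the report itemizes removals per rule.
2. **Richness grids.** Distinct species and genus counts per 0.5° cell,
   and the per-cell species/genus ratio as a diversification surface.
3. **Area of occupancy (AOO).** `AOO = 100 km² × (occupied 10 km × 10 km
   equal-area cells)` per species, plus the percentage of the landmass
   with at least one record.
4. **Protected-area gap analysis.** Each species classified as
   outside-only, inside-only, or both (boundary points count as inside),
   with summary percentages and the number of reserves holding ≥ 1
   species.
5. **Biome tallies and climate space.** Distinct species/genera per
   biome; realized (occupied) vs available (all land cells) climate space
   in mean annual temperature (MAT, °C) × annual precipitation (AP, mm).
6. **Niche breadth.** Per species, `breadth = max − min` of MAT and AP
   over its records; genus-level mean ± SE tables for the top-5 most
   speciose genera vs the pooled remainder.
7. **Comparative statistics.** log₁₀ simple regressions
   (`F = (n−2)R²/(1−R²)`), one-way ANOVA, Tukey-Kramer post hoc tests
   (`q = |m_i − m_j| / √(MSW/2·(1/n_i + 1/n_j))`), collecting effort
   (`log₁₀(records/species)` per taxon), and diversity-vs-land-area
   contrasts with an excluded-region toggle.

Because real national-scale inputs cannot be bundled, the package ships a
first-class **synthetic study-system generator** (`orchidatlas.synth`): a
rectangular continent with smooth MAT/AP gradients, a six-biome climate
partition, a multi-genus species pool with known niche boxes and range
cells, reserve polygons, and injected contamination for every cleaning
rule — all recorded in a truth ledger that downstream stages are tested
against.

## Worked example

The numbered drivers under `analysis/` run the full study at default
scale (~30k raw records, 576 species in 20 genera on a 45° × 35°
continent):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_clean_records.py
python analysis/03_richness_and_aoo.py
python analysis/04_overlays.py
python analysis/05_niche_breadth.py
python analysis/06_comparative_stats.py --seed 1
python analysis/07_power_checks.py
```

Step 02 prints, for seed 1:

```
input rows: 32619, retained: 28488
  rule (a): removed 570
  ...
per-rule counts match the truth ledger exactly: True
```

— the cleaning removed exactly the rows the generator contaminated, and
`input = retained + Σ removed`. Step 05 prints the genus summary table:

```
     Genus19 (n= 56 spp): range  4600 ±  676 km², MAT 4.00 ± 0.24 °C, AP 118.9 ±  5.7 mm
     ...
Remaining genera (n=340 spp): range  4946 ±  277 km², MAT 4.28 ± 0.09 °C, AP 605.0 ± 10.4 mm
```

The five most speciose genera show rainfall breadths of ~110–130 mm
against ~605 mm for the pooled remainder — the narrow-rainfall-niche
signal the generator builds into the speciose genera — and step 06
confirms it statistically (top-5 vs rest, log₁₀ AP breadth:
F(1,574) = 2634, p ≈ 10⁻²¹⁶; all five Tukey-Kramer comparisons against
the pooled rest significant), while finding no such difference for
temperature breadth (p = 0.91). Step 04 shows the desert biome holding 0
species and the climate biplot's hot-and-dry corner empty of occurrence
points although the climate exists on the continent.

A `orchidatlas` command-line interface wraps the same stages
(`simulate`, `clean`, `grid`, `aoo`, `protect`, `biomes`, `niche`,
`stats`, `run`, `simulate-and-run`, `calibrate`); see
`orchidatlas --help`.

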