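# Methods

## Problem and data model

The package converts two inputs into LANDIS-II initial-communities files:

1. a **mapcode raster** — a single-band integer grid (nominally 30 m cells)
   in which each cell holds the identifier of the forest-inventory plot
   imputed to it, with a nodata value for non-forest;
2. a **tree database** — one row per inventory tree (plot id, USDA PLANTS
   species symbol, common name, eastern species-group code, diameter in
   inches, height in feet, alive/dead status) plus a plot table carrying one
   site index per plot.

Two coefficient tables parameterize the allometry: a species reference table
(`SPECIES_SYMBOL, COMMON_NAME, E_SPGRPCD, JENKINS_SPGRPCD, JENKINS_TOTAL_B1,
JENKINS_TOTAL_B2`) and a site-index curve table (`e_spgrpcd, b1..b5`). Both
arrive as user data; choosing which published curve fits a species group is
upstream of this package. The `representative_species` helper implements the
standard reduction used to build such tables: per species-group code, the
species with the most individuals (ties to the lexicographically smallest
symbol, so the result is deterministic and order-independent).

## Biomass

Total aboveground dry biomass per tree follows the Jenkins national-scale
allometry, `bm = exp(B1 + B2 ln(2.54·DIA))` kg, with DIA in inches (2.54
converts to cm). It is undefined at DIA = 0: alive zero-diameter rows
(sub-measurement saplings) are dropped with a logged count rather than
guessed at.

## Age

Age inverts the Carmean-form site-index curve
`H = b1·S^b2·(1 − e^(b3·A))^(b4·S^b5)` (H ft, S site index, A years, b3 < 0
so H rises monotonically to the asymptote `b1·S^b2`):

`A = (1/b3) · ln(1 − (H/(b1·S^b2))^(1/(b4·S^b5)))`.

The forward curve is implemented alongside the inverse, both as the fixture
generator's height model and as the round-trip oracle for the inversion
(recovery to better than 1e-6 relative over the realistic coefficient
ranges). Numerical notes:

* H = 0 returns age 0 exactly (no log evaluation);
* H ≥ asymptote has no finite solution; the age is clamped to `max_age_yr`
  (default 300 yr — old enough for any eastern stand a cohort model will
  see) and a structured `clamped_age` warning is logged. Real inventories
  do contain such trees, so this is a warning, not an error;
* ages are kept as floating point through the tile stage; integer binning
  happens only at cohort assembly.

A tree whose plot lacks a site index, or whose species/group lacks
coefficients, is a hard error naming the plot and species — silent skips
would bias biomass low.

## Tiles

One "landis tile" CSV per plot with at least one alive tree, columns
`MapCode, SPECIES_SYMBOL, COMMON_NAME, E_SPGRPCD, age, biomass`, rows in
input order, MapCode written blank (it is assigned spatially at build time).
A JSON manifest maps plot id → filename so partial reads are cheap.

## Spatial preparation

* **Clipping.** The AOI polygon is reprojected into the raster CRS — never
  the reverse — so imputed cell values stay bit-exact. Cell membership is
  by cell center (deterministic and standard); the output window is the AOI
  bounding box snapped outwards to the source lattice, which makes clipping
  idempotent. Invalid (self-intersecting) AOI geometry is rejected.
* **Mode aggregation.** Optional factor-f coarsening takes the most frequent
  non-nodata value per f×f block, ties to the smallest value (deterministic);
  all-nodata blocks stay nodata; trailing partial blocks aggregate over the
  cells they actually contain. Factor 10 reproduces the 30 m → 300 m product.
* **Remapping.** Distinct surviving plot ids become sequential MapCodes
  1..K in ascending original order; nodata becomes 0, the inactive-cell
  convention of the downstream model. The bijection is returned so tiles
  can be linked back.

## Cohort assembly

Species shares weight each tile's biomass by the pixel count of its MapCode
(each tile stands for exactly one pixel's community; no trees-per-acre
expansion is applied — the raster's imputation already distributes plots
over area). Default selection keeps species with share strictly greater
than 1 % — a screening convention, not an estimate — with explicit
include/exclude overrides; only selected species reach the outputs, and
unselected biomass is dropped, not redistributed.

Ages bin by ceiling to the next timestep multiple, minimum one timestep
(cohort ages must be positive). Ceiling means a 14.97-yr tree lands in the
15-yr class at a 5-yr step. Binning only regroups rows, so pixel-weighted
total biomass is conserved exactly for every timestep choice — the
conservation property the acceptance script measures.

Biomass converts to g/m² as `Σ kg × 1000 / cell_size²`. The wood/leaf split
is a single `leaf_fraction` parameter (default 0: all wood) rather than an
invented foliage allometry; users with a succession extension that needs
leaf mass can supply their own fraction. `--round-int` optionally rounds
the three biomass columns half-away-from-zero, dropping (and counting)
cohorts that round to zero.

MapCodes whose tiles contain no selected species are logged and zeroed in
the output map, so every positive map value has rows in the lookup table.

## I/O and CRS scope

GeoTIFF reading/writing is implemented on tifffile with the standard GeoTIFF
tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA), limited
to the north-up single-band integer layout mapcode rasters use. AOI formats:
GeoJSON, KML, and a minimal ESRI shapefile codec (single polygon, rings
classified by area). Supported CRSs are geographic WGS84 and WGS84/UTM
zones, transformed by the ellipsoidal Transverse Mercator series (Snyder
1987) — sub-millimetre within a zone, micro-degree a few degrees outside it,
verified by round-trip tests. Other projections are out of scope; rasters in
other CRSs should be identified by their EPSG UTM zone or pre-reprojected
with standard GIS tooling.

The pipeline is seed-free and deterministic: identical inputs give
byte-identical CSVs and GeoTIFFs. Stage failures raise errors naming the
stage; the CLI maps them to a nonzero exit. A run log records dropped trees,
clamped ages and empty MapCodes, one structured line per event.

## Synthetic landscape generator

`ricb.fixtures` emulates the statistical shape of an eastern-US imputation
bundle: a 60×60 grid of 30 m cells (UTM 17N), 50 plots with random 5-digit
ids (so remapping is nontrivial), ~30–50 trees per plot from a six-species
pine/oak/maple/poplar pool, site indexes 50–90 ft, diameters 1–30 in, true
ages 5–120 yr, 15 % standing dead, 10 % nodata, and a rotated-rectangle AOI
expressed in geographic WGS84 so the clip must reproject. Heights are drawn
through the *forward* site-index curve from the drawn age, which the tree
table retains as `true_age_yr` — ground truth that makes the age stage's
accuracy directly assertable. Jenkins coefficients are published
species-group values; the site-index coefficients are plausible synthetic
sets shaped like published eastern fits.

What the generator does **not** emulate: spatial autocorrelation of forest
types, realistic stand structure (ages and diameters are drawn
independently), measurement error in heights, or expansion factors. Passing
tests therefore demonstrate the pipeline's arithmetic and contracts, not
imputation quality on real inventories.

## Problem sizes

The test suite and acceptance script run on the 60×60/50-plot landscape
(~2000 trees), 1000-trial allometry oracles, and 100 random grids ≤ 40×40
for the aggregation oracle; the whole suite completes in a few seconds, and
results are identical at any larger size because every stage is exact
arithmetic, not estimation.

## Known limitations

* One polygon per AOI file; multi-feature files use the first feature.
* The shapefile codec reads the first record only and ignores measure/Z
  values.
* No succession-extension-specific dialects (e.g. NECN climate inputs);
  the three output files are the generic initial-communities contract.
* Biomass is raw per-tree Jenkins mass per pixel; if a source database
  carries per-tree expansion factors they must be pre-multiplied upstream.
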