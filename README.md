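# ricb

Build LANDIS-II *initial communities* inputs from a gridded plot-imputation
raster and a forest-inventory tree database.

LANDIS-II simulations start from a pair of inputs describing the landscape at
time zero: an integer **MapCode raster** saying which community occupies each
cell, and a **lookup table** of species–age–biomass cohorts per MapCode.
Assembling these from inventory data is the slowest part of standing up a new
study area. This package automates it for the common setup where a
TreeMap-style imputation raster assigns a forest-inventory plot to every 30 m
pixel and a tree-level database describes each plot.

## Method

Per alive tree, total aboveground dry biomass (kg) comes from the Jenkins
allometry on diameter at breast height (DIA, inches):

```
bm = exp(B1 + B2 · ln(DIA · 2.54))
```

and age (years) from inverting a Carmean-form site-index height curve, where
H is tree height (ft) and S the plot site index:

```
H = b1 · S^b2 · (1 − e^(b3·A))^(b4 · S^b5)     (forward curve, b3 < 0)
A = (1/b3) · ln(1 − (H / (b1·S^b2))^(1/(b4·S^b5)))
```

Heights at or above the site asymptote `b1·S^b2` are clamped to a
configurable maximum age (default 300 yr) with a logged warning. Per-tree
rows are grouped into one "landis tile" CSV per plot.

The spatial build then runs: reproject the AOI polygon into the raster CRS
and clip (cell-center rule; the grid itself is never resampled) → optional
block-mode aggregation (e.g. factor 10: 30 m → 300 m) → remap surviving plot
ids to sequential MapCodes 1..K → rank species by pixel-weighted share of
domain biomass → select species (default: share > 1 %, plus explicit
include/exclude) → bin ages up to the next timestep multiple and sum biomass
per (MapCode, species, age bin), converting kg/pixel to g/m².

Outputs: `ricb_initial_communities.csv`
(`MapCode,SpeciesName,CohortAge,CohortBiomass,WoodBiomass,LeafBiomass`),
`ricb_initial_communities.tif` (0 = inactive cell), and
`parameterization_list.csv` (`SPECIES_SYMBOL,COMMON_NAME`).

## Worked example

No external data is needed: `ricb synth` generates a complete synthetic
landscape (raster, tree/plot/coefficient tables, AOI, prebuilt tiles) with
known ground truth, and `ricb build` runs the pipeline on it.

```
$ ricb synth --out demo --seed 1
wrote landscape (60x60, 50 plots, seed 1) and 50 landis tiles under demo

$ ricb build --raster demo/mapcodes.tif --tiles demo/landis_tiles \
             --aoi demo/aoi.geojson --out demo/out --timestep 10
built 1412 cohorts for 6 species over 50 map codes

$ head -4 demo/out/ricb_initial_communities.csv
MapCode,SpeciesName,CohortAge,CohortBiomass,WoodBiomass,LeafBiomass
1,ACRU,10,1758.994586189283,1758.994586189283,0
1,ACRU,20,832.7674169323842,832.7674169323842,0
1,ACRU,40,557.6546466327758,557.6546466327758,0
```

Row one says: cells with MapCode 1 start with a red-maple (ACRU) cohort of
age-class ≤ 10 yr carrying 1759 g/m² of aboveground biomass (all wood, since
the default leaf fraction is 0). `demo/out/parameterization_list.csv` lists
the six selected species with common names, and every positive value in the
GeoTIFF has matching rows in the CSV.

Useful flags: `--factor 10` (coarsen by mode), `--threshold`, `--include` /
`--exclude` (repeatable), `--leaf-fraction`, `--round-int` (integer biomass,
zero-rounding cohorts dropped), `--overwrite`, `--interactive` (print the
species abundance lists).

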