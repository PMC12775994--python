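"""Synthetic landscape and inventory generator.

Produces the full input bundle the pipeline consumes — a mapcode raster, a
tree table, a plot table, a species reference table, a site-index
coefficient table, and an area-of-interest polygon — with known ground
truth, so every stage is testable without any national inventory download.

Design points that make the outputs useful as test oracles:

* tree heights are generated through the *forward* site-index curve from a
  drawn true age (kept in the tree table as ``true_age_yr``), so the age
  inversion downstream has a known exact answer;
* plot identifiers are random non-sequential 5-digit integers, so the
  sequential remap is exercised nontrivially;
* the AOI is a rotated rectangle covering a strict subset of the grid and
  is expressed in geographic WGS84 while the raster is in a UTM zone, so
  the clip stage must reproject.

Defaults emulate an eastern-US mixed pine/hardwood inventory: ~50 plots of
30–50 trees on a 60×60 grid of 30 m cells, site indexes 50–90 ft, stand
ages 5–120 yr, 15 % standing dead stems, 10 % non-forest (nodata) cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import aoi as aoi_io
from .allometry import CarmeanCoefficients, carmean_height
from .crs import transform_points
from .geotiff import write_geotiff
from .raster import MapcodeRaster

__all__ = ["FixtureConfig", "Landscape", "generate_landscape", "write_landscape"]

# (symbol, common name, eastern species group code, Jenkins B1, Jenkins B2)
DEFAULT_SPECIES_POOL = [
    ("PITA", "loblolly pine", 2, -2.5356, 2.4349),
    ("QUNI", "water oak", 28, -2.4800, 2.4835),
    ("QULA3", "laurel oak", 28, -2.4800, 2.4835),
    ("ACRU", "red maple", 32, -1.9123, 2.3651),
    ("QUAL", "white oak", 25, -2.0127, 2.4342),
    ("LITU", "yellow-poplar", 39, -2.4800, 2.4835),
]

# per species group: (b1, b2, b3, b4, b5), shaped like published eastern
# site-index curve fits (asymptote b1*SI^b2 in feet, decay rate b3 < 0)
DEFAULT_CARMEAN_POOL = {
    2: (1.1421, 0.9947, -0.0269, 1.0753, -0.0119),
    25: (1.2934, 0.9888, -0.0322, 1.2897, -0.0084),
    28: (1.2866, 0.9962, -0.0355, 1.4485, -0.0316),
    32: (2.9435, 0.9132, -0.0141, 1.6580, -0.1095),
    39: (1.2673, 0.9995, -0.0254, 1.1149, -0.0109),
}


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    grid_rows: int = 60
    grid_cols: int = 60
    cell_size_m: float = 30.0
    n_plots: int = 50
    species_pool: list = field(default_factory=lambda: list(DEFAULT_SPECIES_POOL))
    carmean_pool: dict = field(default_factory=lambda: dict(DEFAULT_CARMEAN_POOL))
    nodata_fraction: float = 0.10
    trees_per_plot_range: tuple[int, int] = (30, 50)
    dead_fraction: float = 0.15
    site_index_range: tuple[float, float] = (50.0, 90.0)
    dia_range_in: tuple[float, float] = (1.0, 30.0)
    true_age_range_yr: tuple[float, float] = (5.0, 120.0)
    crs_id: str = "EPSG:32617"
    origin_x: float = 500_000.0
    origin_y: float = 3_900_000.0
    nodata: int = -9999

    def validate(self) -> None:
        for name in ("trees_per_plot_range", "site_index_range", "dia_range_in", "true_age_range_yr"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {lo} > {hi}")
        for name in ("nodata_fraction", "dead_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_plots < 1 or self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("n_plots and grid dimensions must be positive")
        missing = {
            grp for _, _, grp, _, _ in self.species_pool if grp not in self.carmean_pool
        }
        if missing:
            raise ValueError(
                f"species groups without site-index coefficients: {sorted(missing)}"
            )


@dataclass
class Landscape:
    """The generated input bundle plus its ground truth."""

    raster: MapcodeRaster
    trees: pd.DataFrame  # plot_id, species_symbol, common_name, e_spgrpcd,
    #                      dia_in, ht_ft, alive, true_age_yr (ground truth)
    plots: pd.DataFrame  # plot_id, site_index
    species_ref: pd.DataFrame  # Table-1-shaped species reference
    carmean: pd.DataFrame  # e_spgrpcd, b1..b5
    aoi: Polygon
    aoi_crs: str


def _make_aoi(config: FixtureConfig) -> Polygon:
    """Rotated rectangle over the grid interior, expressed in WGS84."""
    width = config.grid_cols * config.cell_size_m
    height = config.grid_rows * config.cell_size_m
    cx = config.origin_x + width / 2
    cy = config.origin_y - height / 2
    hw, hh = 0.36 * width, 0.36 * height
    theta = np.radians(20.0)
    corners = np.array([(-hw, -hh), (hw, -hh), (hw, hh), (-hw, hh), (-hw, -hh)])
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    pts = corners @ rot.T + [cx, cy]
    lon, lat = transform_points(pts[:, 0], pts[:, 1], config.crs_id, "EPSG:4326")
    return Polygon(zip(lon, lat))


def generate_landscape(config: FixtureConfig) -> Landscape:
    """Draw a complete synthetic landscape; equal seeds give equal outputs."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    plot_ids = np.sort(
        rng.choice(np.arange(10_000, 100_000), size=config.n_plots, replace=False)
    )

    grid = rng.choice(plot_ids, size=(config.grid_rows, config.grid_cols))
    nodata_mask = rng.random(grid.shape) < config.nodata_fraction
    grid = np.where(nodata_mask, config.nodata, grid).astype(np.int32)
    raster = MapcodeRaster(
        grid,
        config.nodata,
        config.origin_x,
        config.origin_y,
        config.cell_size_m,
        config.crs_id,
    )

    si_lo, si_hi = config.site_index_range
    site_index = rng.uniform(si_lo, si_hi, size=config.n_plots)
    plots = pd.DataFrame({"plot_id": plot_ids, "site_index": site_index})

    carmean_coeffs = {
        grp: CarmeanCoefficients(*vals) for grp, vals in config.carmean_pool.items()
    }
    n_lo, n_hi = config.trees_per_plot_range
    rows = []
    for pid, si in zip(plot_ids, site_index):
        n_trees = int(rng.integers(n_lo, n_hi + 1))
        for _ in range(n_trees):
            sym, name, grp, _, _ = config.species_pool[
                int(rng.integers(len(config.species_pool)))
            ]
            dia = float(rng.uniform(*config.dia_range_in))
            age = float(rng.uniform(*config.true_age_range_yr))
            ht = carmean_height(age, float(si), carmean_coeffs[grp])
            alive = bool(rng.random() >= config.dead_fraction)
            rows.append((int(pid), sym, name, grp, dia, ht, alive, age))
    trees = pd.DataFrame(
        rows,
        columns=[
            "plot_id",
            "species_symbol",
            "common_name",
            "e_spgrpcd",
            "dia_in",
            "ht_ft",
            "alive",
            "true_age_yr",
        ],
    )

    species_ref = pd.DataFrame(
        [
            (sym, name, grp, grp, b1, b2)
            for sym, name, grp, b1, b2 in config.species_pool
        ],
        columns=[
            "SPECIES_SYMBOL",
            "COMMON_NAME",
            "E_SPGRPCD",
            "JENKINS_SPGRPCD",
            "JENKINS_TOTAL_B1",
            "JENKINS_TOTAL_B2",
        ],
    )
    carmean = pd.DataFrame(
        [(grp, *vals) for grp, vals in sorted(config.carmean_pool.items())],
        columns=["e_spgrpcd", "b1", "b2", "b3", "b4", "b5"],
    )

    return Landscape(
        raster=raster,
        trees=trees,
        plots=plots,
        species_ref=species_ref,
        carmean=carmean,
        aoi=_make_aoi(config),
        aoi_crs="EPSG:4326",
    )


def write_landscape(land: Landscape, out_dir) -> dict[str, Path]:
    """Serialize the bundle: GeoTIFF raster, CSV tables, GeoJSON + shapefile AOI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "raster": out_dir / "mapcodes.tif",
        "trees": out_dir / "trees.csv",
        "plots": out_dir / "plots.csv",
        "species_ref": out_dir / "species_reference.csv",
        "carmean": out_dir / "carmean_coefficients.csv",
        "aoi_geojson": out_dir / "aoi.geojson",
        "aoi_shp": out_dir / "aoi.shp",
    }
    write_geotiff(land.raster, paths["raster"])
    land.trees.to_csv(paths["trees"], index=False)
    land.plots.to_csv(paths["plots"], index=False)
    land.species_ref.to_csv(paths["species_ref"], index=False)
    land.carmean.to_csv(paths["carmean"], index=False)
    aoi_io.write_geojson(land.aoi, land.aoi_crs, paths["aoi_geojson"])
    aoi_io.write_shapefile(land.aoi, land.aoi_crs, paths["aoi_shp"])
    return paths
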