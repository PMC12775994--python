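"""Output writers and the end-to-end build pipeline.

The pipeline runs clip → (optional mode aggregation) → sequential remap →
species abundance → species selection → cohort assembly, then writes the
three deliverables a LANDIS-II run needs:

* ``ricb_initial_communities.csv`` — the cohort lookup table
  (MapCode, SpeciesName, CohortAge, CohortBiomass, WoodBiomass, LeafBiomass);
* ``ricb_initial_communities.tif`` — the map linking cells to MapCodes
  (0 = inactive cell);
* ``parameterization_list.csv`` — the selected species and their common
  names, for succession-extension parameterization.

Everything is deterministic: identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .aoi import read_aoi
from .cohorts import (
    CohortRecord,
    SpeciesSummary,
    build_cohorts,
    round_cohorts,
    select_species,
    species_abundance,
)
from .geotiff import read_geotiff, write_geotiff
from .raster import MapcodeRaster, clip_to_aoi, mode_aggregate, remap_sequential
from .tiles import read_tiles

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "PipelineStageError",
    "COHORT_HEADER",
    "write_initial_communities",
    "write_map",
    "write_parameterization_list",
    "run_pipeline",
]

COHORT_HEADER = [
    "MapCode",
    "SpeciesName",
    "CohortAge",
    "CohortBiomass",
    "WoodBiomass",
    "LeafBiomass",
]

COMMUNITIES_CSV = "ricb_initial_communities.csv"
COMMUNITIES_TIF = "ricb_initial_communities.tif"
PARAM_LIST_CSV = "parameterization_list.csv"
RUN_LOG = "ricb_run.log"


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    raster_path: Path
    tiles_dir: Path
    aoi_path: Path
    out_dir: Path
    resolution_factor: int = 1
    timestep: int = 10
    threshold: float = 0.01
    include: tuple[str, ...] = ()
    exclude: tuple[str, ...] = ()
    leaf_fraction: float = 0.0
    round_int: bool = False
    overwrite: bool = False

    def validate(self) -> None:
        for name in ("raster_path", "tiles_dir", "aoi_path"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name}: {getattr(self, name)} does not exist")
        if self.timestep < 1:
            raise ValueError(f"timestep must be >= 1, got {self.timestep}")
        if self.resolution_factor < 1:
            raise ValueError(
                f"resolution factor must be >= 1, got {self.resolution_factor}"
            )
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0,1], got {self.threshold}")


@dataclass
class PipelineResult:
    records: list[CohortRecord]
    summaries: list[SpeciesSummary]
    selected: set[str]
    raster: MapcodeRaster
    outputs: dict[str, Path] = field(default_factory=dict)


def _format_number(x: float) -> str:
    """Full-precision but human-stable float formatting (ints print bare)."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_initial_communities(records: Sequence[CohortRecord], path) -> None:
    """Write the cohort lookup table CSV (warns when empty)."""
    if not records:
        logger.warning("writing header-only initial-communities file: no cohorts")
    rows = [
        {
            "MapCode": r.map_code,
            "SpeciesName": r.species_symbol,
            "CohortAge": r.cohort_age_yr,
            "CohortBiomass": _format_number(r.cohort_biomass_g_m2),
            "WoodBiomass": _format_number(r.wood_biomass_g_m2),
            "LeafBiomass": _format_number(r.leaf_biomass_g_m2),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COHORT_HEADER).to_csv(path, index=False)


def write_map(raster: MapcodeRaster, path) -> None:
    """Write the MapCode raster (sequential codes, 0 = inactive) as GeoTIFF."""
    if raster.nodata != 0:
        raise ValueError("map raster must be remapped (nodata 0) before writing")
    vals = raster.grid[raster.grid != 0]
    if vals.size and (vals.min() < 1):
        raise ValueError("map raster values must be 0..K")
    write_geotiff(raster, path)


def write_parameterization_list(
    summaries: Sequence[SpeciesSummary], selected: set[str], path
) -> None:
    """Write the selected species list (symbol, common name), sorted by symbol."""
    if not selected:
        logger.warning("writing header-only parameterization list: nothing selected")
    rows = sorted(
        (s.species_symbol, s.common_name) for s in summaries if s.species_symbol in selected
    )
    pd.DataFrame(rows, columns=["SPECIES_SYMBOL", "COMMON_NAME"]).to_csv(
        path, index=False
    )


def _stage(name):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full build and write the three output files.

    Refuses to touch an output directory that already holds build products
    unless ``overwrite`` is set.  Any stage failure raises
    :class:`PipelineStageError` naming the stage.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    existing = [
        n
        for n in (COMMUNITIES_CSV, COMMUNITIES_TIF, PARAM_LIST_CSV)
        if (out_dir / n).exists()
    ]
    if existing and not config.overwrite:
        raise FileExistsError(
            f"{out_dir} already contains {existing}; pass overwrite to replace"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out_dir / RUN_LOG, mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("ricb")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        with _stage("read-raster"):
            raster = read_geotiff(config.raster_path)
        with _stage("read-aoi"):
            aoi, aoi_crs = read_aoi(config.aoi_path)
        with _stage("clip"):
            clipped = clip_to_aoi(raster, aoi, aoi_crs)
        if config.resolution_factor > 1:
            with _stage("mode-aggregate"):
                clipped = mode_aggregate(clipped, config.resolution_factor)
        with _stage("remap"):
            remapped, remap = remap_sequential(clipped)
        with _stage("read-tiles"):
            tiles = read_tiles(config.tiles_dir, plot_ids=list(remap.to_sequential))
        with _stage("abundance"):
            summaries = species_abundance(tiles, remapped, remap)
        with _stage("select"):
            selected = select_species(
                summaries, config.threshold, config.include, config.exclude
            )
        with _stage("cohorts"):
            records = build_cohorts(
                tiles,
                remapped,
                remap,
                selected,
                config.timestep,
                config.leaf_fraction,
            )
            if config.round_int:
                records = round_cohorts(records)
        with _stage("write-outputs"):
            # cells whose map code yielded no cohorts become inactive (0) so
            # every positive value in the map has rows in the lookup table
            active = {r.map_code for r in records}
            grid = remapped.grid.copy()
            grid[~np.isin(grid, sorted(active))] = 0
            out_raster = MapcodeRaster(
                grid,
                0,
                remapped.origin_x,
                remapped.origin_y,
                remapped.cell_size_m,
                remapped.crs_id,
            )
            outputs = {
                "communities_csv": out_dir / COMMUNITIES_CSV,
                "communities_tif": out_dir / COMMUNITIES_TIF,
                "parameterization_csv": out_dir / PARAM_LIST_CSV,
                "log": out_dir / RUN_LOG,
            }
            write_initial_communities(records, outputs["communities_csv"])
            write_map(out_raster, outputs["communities_tif"])
            write_parameterization_list(
                summaries, selected, outputs["parameterization_csv"]
            )
        return PipelineResult(records, summaries, selected, out_raster, outputs)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
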