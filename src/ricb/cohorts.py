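"""Species selection and species-age-biomass cohort assembly.

This is the core of the initial-communities build.  Given the clipped,
remapped mapcode raster and the landis tiles it references:

1. rank every species by its share of domain-wide aboveground biomass,
   weighting each tile's biomass by how many pixels carry its map code;
2. select the species to parameterize (by default those above 1 % of total
   biomass, with explicit include/exclude overrides);
3. bin tree ages up to the next multiple of the simulation timestep and sum
   biomass within each (map code, species, age bin), converting kilograms
   per pixel to g/m² by dividing by the pixel area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .raster import MapcodeRaster, RemapTable
from .tiles import LandisTile

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesSummary",
    "CohortRecord",
    "species_abundance",
    "select_species",
    "bin_age",
    "build_cohorts",
    "round_cohorts",
]


@dataclass(frozen=True)
class SpeciesSummary:
    """Domain-wide, pixel-weighted biomass total and share for one species."""

    species_symbol: str
    common_name: str
    total_biomass_kg: float
    fraction: float


@dataclass(frozen=True)
class CohortRecord:
    """One output row: a species-age cohort on one map code, in g/m²."""

    map_code: int
    species_symbol: str
    cohort_age_yr: int
    cohort_biomass_g_m2: float
    wood_biomass_g_m2: float
    leaf_biomass_g_m2: float


def _pixel_counts_by_plot(
    raster: MapcodeRaster, remap: RemapTable
) -> dict[int, int]:
    """Original plot id -> pixel count, from the remapped raster."""
    out = {}
    for seq_code, n in raster.value_counts().items():
        if seq_code not in remap.to_original:
            raise KeyError(f"raster code {seq_code} is absent from the remap table")
        out[remap.to_original[seq_code]] = n
    return out


def species_abundance(
    tiles: Mapping[int, LandisTile],
    raster: MapcodeRaster,
    remap: RemapTable,
) -> list[SpeciesSummary]:
    """Rank species by pixel-weighted share of total domain biomass.

    Each tile describes one pixel's worth of trees, so a plot covering n
    pixels contributes n times its per-tree biomass.  Fractions are
    normalized by the grand total over *all* species, selected or not.
    Raises on a raster code with no tile and on a domain with no biomass.
    """
    counts = _pixel_counts_by_plot(raster, remap)
    totals: dict[str, float] = {}
    names: dict[str, str] = {}
    for plot_id, n_pixels in sorted(counts.items()):
        if plot_id not in tiles:
            raise KeyError(f"no landis tile for raster plot id {plot_id}")
        for r in tiles[plot_id].frame.itertuples():
            sym = str(r.SPECIES_SYMBOL)
            totals[sym] = totals.get(sym, 0.0) + float(r.biomass) * n_pixels
            names.setdefault(sym, str(r.COMMON_NAME))
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("domain contains no alive-tree biomass")
    summaries = [
        SpeciesSummary(sym, names[sym], total, total / grand)
        for sym, total in totals.items()
    ]
    summaries.sort(key=lambda s: (-s.fraction, s.species_symbol))
    return summaries


def select_species(
    summaries: Sequence[SpeciesSummary],
    threshold: float = 0.01,
    include: Iterable[str] = (),
    exclude: Iterable[str] = (),
) -> set[str]:
    """Choose the species that will appear in the initial-communities file.

    Default rule: biomass fraction strictly greater than ``threshold``
    (1 % unless overridden).  ``include`` forces species in — the hook for
    admitting ecologically relevant species below the cutoff — and
    ``exclude`` forces them out.  Only selected species survive to the
    output files.
    """
    known = {s.species_symbol for s in summaries}
    include = set(include)
    exclude = set(exclude)
    unknown = sorted(include - known)
    if unknown:
        raise ValueError(f"include lists species absent from the domain: {unknown}")
    selected = {s.species_symbol for s in summaries if s.fraction > threshold}
    return (selected | include) - exclude


def bin_age(age_yr: float, timestep: int) -> int:
    """Bin an age up to the next multiple of the timestep (minimum one step)."""
    if timestep < 1:
        raise ValueError(f"timestep must be >= 1, got {timestep}")
    if age_yr < 0:
        raise ValueError(f"age must be nonnegative, got {age_yr}")
    return max(int(math.ceil(age_yr / timestep)), 1) * timestep


def build_cohorts(
    tiles: Mapping[int, LandisTile],
    raster: MapcodeRaster,
    remap: RemapTable,
    selected: set[str],
    timestep: int,
    leaf_fraction: float = 0.0,
) -> list[CohortRecord]:
    """Assemble the species-age-biomass cohorts for every map code.

    Within each map code, trees of a selected species falling in the same
    age bin are pooled: biomass sums in kilograms, then converts to g/m²
    against the pixel area (each tile stands for one pixel).  The leaf
    fraction splits each cohort's total into leaf and wood components.
    Map codes whose tiles contain no selected species produce no records
    (logged).
    """
    if timestep < 1:
        raise ValueError(f"timestep must be >= 1, got {timestep}")
    if not 0.0 <= leaf_fraction <= 1.0:
        raise ValueError(f"leaf_fraction must be in [0, 1], got {leaf_fraction}")
    cell_area_m2 = raster.cell_size_m**2

    records: list[CohortRecord] = []
    present_codes = sorted(raster.value_counts())
    for code in present_codes:
        plot_id = remap.to_original[code]
        if plot_id not in tiles:
            raise KeyError(f"no landis tile for raster plot id {plot_id}")
        frame = tiles[plot_id].frame
        kept = frame[frame["SPECIES_SYMBOL"].isin(selected)]
        if kept.empty:
            logger.warning("empty_mapcode map code %d (plot %d): no selected species", code, plot_id)
            continue
        bins = kept["age"].map(lambda a: bin_age(float(a), timestep))
        grouped = kept.assign(cohort_age=bins).groupby(
            ["SPECIES_SYMBOL", "cohort_age"], sort=True
        )["biomass"].sum()
        for (sym, age), kg in grouped.items():
            total = float(kg) * 1000.0 / cell_area_m2
            leaf = leaf_fraction * total
            records.append(
                CohortRecord(code, str(sym), int(age), total, total - leaf, leaf)
            )
    records.sort(key=lambda r: (r.map_code, r.species_symbol, r.cohort_age_yr))
    return records


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def round_cohorts(records: Sequence[CohortRecord]) -> list[CohortRecord]:
    """Round biomass columns to integers, dropping cohorts that round to zero.

    Rounding is half away from zero; the dropped-cohort count is logged.
    """
    out = []
    dropped = 0
    for r in records:
        total = _round_half_away(r.cohort_biomass_g_m2)
        if total == 0:
            dropped += 1
            continue
        leaf = _round_half_away(r.leaf_biomass_g_m2)
        out.append(
            CohortRecord(
                r.map_code, r.species_symbol, r.cohort_age_yr, total, total - leaf, leaf
            )
        )
    if dropped:
        logger.warning("dropped %d cohort(s) whose biomass rounded to zero", dropped)
    return out
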