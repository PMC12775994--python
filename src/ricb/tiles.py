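"""Per-plot "landis tile" construction and serialization.

A landis tile is the per-plot table of per-tree (species, age, biomass)
rows from which map-cell cohorts are later assembled.  One tile is built
per inventory plot containing at least one alive tree: dead trees are
excluded, biomass comes from the Jenkins allometry on diameter, and age
from inverting the plot's site-index height curve.

Tiles serialize as one CSV per plot (``<tiles_dir>/<plot_id>.csv``) with the
columns ``MapCode, SPECIES_SYMBOL, COMMON_NAME, E_SPGRPCD, age, biomass``.
The MapCode column is written blank; it is a placeholder filled by the
spatial linkage stage downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .allometry import (
    CarmeanCoefficients,
    JenkinsCoefficients,
    PlotRecord,
    TreeRecord,
    carmean_age,
    jenkins_biomass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LandisTile",
    "TILE_COLUMNS",
    "augment_and_build_tiles",
    "write_tile",
    "read_tile",
    "write_tiles",
    "read_tiles",
]

TILE_COLUMNS = ["MapCode", "SPECIES_SYMBOL", "COMMON_NAME", "E_SPGRPCD", "age", "biomass"]
MANIFEST_NAME = "tiles_manifest.json"


@dataclass
class LandisTile:
    """Per-plot table of per-tree species/age/biomass rows."""

    plot_id: int
    frame: pd.DataFrame  # columns TILE_COLUMNS

    def __post_init__(self):
        missing = [c for c in TILE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"tile {self.plot_id} missing columns {missing}")
        self.frame = self.frame[TILE_COLUMNS].reset_index(drop=True)
        if (self.frame["biomass"] < 0).any() or (self.frame["age"] < 0).any():
            raise ValueError(f"tile {self.plot_id} has negative age or biomass")

    def __eq__(self, other):
        if not isinstance(other, LandisTile):
            return NotImplemented
        return self.plot_id == other.plot_id and self.frame.equals(other.frame)


def _as_tree_records(trees) -> list[TreeRecord]:
    if isinstance(trees, pd.DataFrame):
        return [
            TreeRecord(
                int(r.plot_id),
                str(r.species_symbol),
                str(r.common_name),
                int(r.e_spgrpcd),
                float(r.dia_in),
                float(r.ht_ft),
                bool(r.alive),
            )
            for r in trees.itertuples()
        ]
    return list(trees)


def _as_plot_map(plots) -> dict[int, float]:
    if isinstance(plots, pd.DataFrame):
        return {int(r.plot_id): float(r.site_index) for r in plots.itertuples()}
    return {p.plot_id: p.site_index for p in plots}


def augment_and_build_tiles(
    trees: Iterable[TreeRecord] | pd.DataFrame,
    plots: Iterable[PlotRecord] | pd.DataFrame,
    jenkins_table: Mapping[str, JenkinsCoefficients],
    carmean_table: Mapping[int, CarmeanCoefficients],
    max_age_yr: float = 300.0,
) -> dict[int, LandisTile]:
    """Compute per-tree age and biomass and group the rows into tiles.

    Dead trees are excluded.  An alive tree whose plot lacks a site index,
    whose species lacks Jenkins coefficients, or whose species group lacks
    Carmean coefficients is a hard error naming the plot/species.  Alive
    trees with zero diameter are dropped with a logged count (the biomass
    allometry is undefined at zero); zero height gives age zero.
    """
    site_index = _as_plot_map(plots)
    rows_by_plot: dict[int, list] = {}
    dropped_zero_dia = 0
    for t in _as_tree_records(trees):
        if not t.alive:
            continue
        if t.plot_id not in site_index:
            raise KeyError(f"plot {t.plot_id} has no site-index record")
        if t.species_symbol not in jenkins_table:
            raise KeyError(
                f"species {t.species_symbol} (plot {t.plot_id}) has no Jenkins coefficients"
            )
        if t.e_spgrpcd not in carmean_table:
            raise KeyError(
                f"species group {t.e_spgrpcd} (species {t.species_symbol}, plot "
                f"{t.plot_id}) has no Carmean coefficients"
            )
        if t.dia_in == 0:
            dropped_zero_dia += 1
            continue
        biomass = jenkins_biomass(t.dia_in, jenkins_table[t.species_symbol])
        age = carmean_age(
            t.ht_ft, site_index[t.plot_id], carmean_table[t.e_spgrpcd], max_age_yr
        )
        rows_by_plot.setdefault(t.plot_id, []).append(
            {
                "MapCode": pd.NA,
                "SPECIES_SYMBOL": t.species_symbol,
                "COMMON_NAME": t.common_name,
                "E_SPGRPCD": t.e_spgrpcd,
                "age": age,
                "biomass": biomass,
            }
        )
    if dropped_zero_dia:
        logger.warning("dropped_tree zero-diameter alive trees: %d", dropped_zero_dia)
    return {
        pid: LandisTile(pid, pd.DataFrame(rows, columns=TILE_COLUMNS))
        for pid, rows in rows_by_plot.items()
    }


def write_tile(tile: LandisTile, path) -> None:
    """Write one tile CSV; the MapCode column is left blank."""
    out = tile.frame.copy()
    out["MapCode"] = ""
    out.to_csv(path, index=False)


def read_tile(path, plot_id: int | None = None) -> LandisTile:
    """Read one tile CSV; raises a format error naming any missing column."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tile file {path} missing column(s) {missing}")
    if plot_id is None:
        plot_id = int(path.stem)
    df["MapCode"] = pd.NA
    df["E_SPGRPCD"] = df["E_SPGRPCD"].astype(int)
    return LandisTile(plot_id, df)


def write_tiles(tiles: Mapping[int, LandisTile], tiles_dir) -> None:
    """Write every tile as ``<tiles_dir>/<plot_id>.csv`` plus a manifest."""
    tiles_dir = Path(tiles_dir)
    tiles_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for pid in sorted(tiles):
        fname = f"{pid}.csv"
        write_tile(tiles[pid], tiles_dir / fname)
        manifest[str(pid)] = fname
    (tiles_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2) + "\n")


def read_tiles(tiles_dir, plot_ids: Sequence[int] | None = None) -> dict[int, LandisTile]:
    """Read tiles from a directory, via its manifest when present.

    If ``plot_ids`` is given, only those tiles are loaded (missing ones are
    a KeyError naming the plot).
    """
    tiles_dir = Path(tiles_dir)
    manifest_path = tiles_dir / MANIFEST_NAME
    if manifest_path.exists():
        manifest = {int(k): v for k, v in json.loads(manifest_path.read_text()).items()}
    else:
        manifest = {int(p.stem): p.name for p in sorted(tiles_dir.glob("*.csv"))}
    wanted = sorted(manifest) if plot_ids is None else sorted(set(plot_ids))
    out = {}
    for pid in wanted:
        if pid not in manifest:
            raise KeyError(f"no landis tile for plot {pid} in {tiles_dir}")
        out[pid] = read_tile(tiles_dir / manifest[pid], plot_id=pid)
    return out
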