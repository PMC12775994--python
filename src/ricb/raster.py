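"""Mapcode raster container and spatial preparation operations.

A mapcode raster is a single-band integer grid in which every non-nodata
cell holds the identifier of the inventory plot imputed to that cell.  The
operations here prepare such a raster for cohort assembly: clip it to a
user's area of interest (AOI), optionally coarsen it by block mode, and
remap the surviving plot identifiers to the sequential 1..K map codes the
downstream lookup table uses.

The grid is never resampled or reprojected — the AOI polygon is transformed
into the raster CRS instead, so imputed cell values stay bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .crs import normalize_crs, transform_points

__all__ = [
    "MapcodeRaster",
    "RemapTable",
    "ClipError",
    "GeometryError",
    "clip_to_aoi",
    "remap_sequential",
    "mode_aggregate",
]


class ClipError(ValueError):
    """AOI and raster do not overlap, or the clip result is empty."""


class GeometryError(ValueError):
    """AOI geometry is unreadable, invalid, or not polygonal."""


@dataclass(eq=False)
class MapcodeRaster:
    """Integer plot-identifier grid with georeferencing.

    ``origin_x``/``origin_y`` locate the *outer corner of the top-left
    cell* (row 0, col 0); rows increase southwards, the usual north-up
    raster layout.
    """

    grid: np.ndarray
    nodata: int
    origin_x: float
    origin_y: float
    cell_size_m: float
    crs_id: str

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int32)
        if self.grid.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {self.grid.shape}")
        if self.cell_size_m <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell_size_m}")
        self.crs_id = normalize_crs(self.crs_id)
        data = self.grid[self.grid != self.nodata]
        if data.size and data.min() <= 0:
            raise ValueError("non-nodata mapcode values must be positive")

    def __eq__(self, other):
        if not isinstance(other, MapcodeRaster):
            return NotImplemented
        return (
            np.array_equal(self.grid, other.grid)
            and self.nodata == other.nodata
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.cell_size_m == other.cell_size_m
            and self.crs_id == other.crs_id
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the grid footprint in map units."""
        rows, cols = self.grid.shape
        return (
            self.origin_x,
            self.origin_y - rows * self.cell_size_m,
            self.origin_x + cols * self.cell_size_m,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of every cell-center coordinate."""
        rows, cols = self.grid.shape
        xs = self.origin_x + (np.arange(cols) + 0.5) * self.cell_size_m
        ys = self.origin_y - (np.arange(rows) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)

    def value_counts(self) -> dict[int, int]:
        """Pixel count per non-nodata value."""
        vals, counts = np.unique(self.grid[self.grid != self.nodata], return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass(frozen=True)
class RemapTable:
    """Bijection between original plot identifiers and sequential map codes 1..K."""

    to_sequential: Mapping[int, int]
    to_original: Mapping[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        inv = {s: o for o, s in self.to_sequential.items()}
        if len(inv) != len(self.to_sequential):
            raise ValueError("remap table is not a bijection")
        if sorted(inv) != list(range(1, len(inv) + 1)):
            raise ValueError("sequential codes must be exactly 1..K")
        object.__setattr__(self, "to_original", inv)

    def __len__(self):
        return len(self.to_sequential)


def _reproject_polygon(aoi: Polygon, aoi_crs: str, dst_crs: str) -> Polygon:
    def _tx(coords: np.ndarray) -> np.ndarray:
        x, y = transform_points(coords[:, 0], coords[:, 1], aoi_crs, dst_crs)
        return np.column_stack([x, y])

    return shapely.transform(aoi, _tx)


def clip_to_aoi(raster: MapcodeRaster, aoi: Polygon, aoi_crs: str) -> MapcodeRaster:
    """Clip the raster to an AOI polygon given in any supported CRS.

    The AOI is reprojected into the raster CRS; the raster grid is never
    touched.  Cells whose *centers* fall outside the AOI become nodata, and
    the output extent is the AOI bounding box snapped outwards to the source
    grid, so repeated clips with the same AOI are idempotent.
    """
    if aoi is None or aoi.is_empty:
        raise GeometryError("AOI geometry is empty")
    if not isinstance(aoi, (Polygon,)) and aoi.geom_type != "MultiPolygon":
        raise GeometryError(f"AOI must be polygonal, got {aoi.geom_type}")
    if not aoi.is_valid:
        raise GeometryError("AOI geometry is corrupt (self-intersecting or invalid)")

    poly = _reproject_polygon(aoi, aoi_crs, raster.crs_id)
    minx, miny, maxx, maxy = raster.bounds
    if not poly.intersects(box(minx, miny, maxx, maxy)):
        raise ClipError("AOI does not intersect the raster extent")

    cs = raster.cell_size_m
    pminx, pminy, pmaxx, pmaxy = poly.bounds
    # snap AOI bbox outwards onto the source grid lattice
    c0 = max(0, int(np.floor((pminx - raster.origin_x) / cs)))
    c1 = min(raster.grid.shape[1], int(np.ceil((pmaxx - raster.origin_x) / cs)))
    r0 = max(0, int(np.floor((raster.origin_y - pmaxy) / cs)))
    r1 = min(raster.grid.shape[0], int(np.ceil((raster.origin_y - pminy) / cs)))
    if c0 >= c1 or r0 >= r1:
        raise ClipError("AOI bounding box covers no raster cells")

    window = raster.grid[r0:r1, c0:c1].copy()
    new_ox = raster.origin_x + c0 * cs
    new_oy = raster.origin_y - r0 * cs

    xs = new_ox + (np.arange(window.shape[1]) + 0.5) * cs
    ys = new_oy - (np.arange(window.shape[0]) + 0.5) * cs
    xg, yg = np.meshgrid(xs, ys)
    inside = shapely.intersects_xy(poly, xg.ravel(), yg.ravel()).reshape(window.shape)
    window[~inside] = raster.nodata

    if not np.any(window != raster.nodata):
        raise ClipError("clip produced no data cells inside the AOI")
    return MapcodeRaster(
        window, raster.nodata, new_ox, new_oy, cs, raster.crs_id
    )


def remap_sequential(raster: MapcodeRaster) -> tuple[MapcodeRaster, RemapTable]:
    """Replace distinct plot identifiers by sequential codes 1..K.

    Codes are assigned in ascending order of the original value.  Nodata
    cells become 0 in the output (the inactive-cell convention of the
    downstream landscape model), and the output raster's nodata is 0.
    """
    data_mask = raster.grid != raster.nodata
    originals = np.unique(raster.grid[data_mask])
    if originals.size == 0:
        raise ClipError("raster contains no data cells to remap")
    table = RemapTable({int(o): i + 1 for i, o in enumerate(originals)})
    out = np.zeros_like(raster.grid)
    out[data_mask] = np.searchsorted(originals, raster.grid[data_mask]) + 1
    return (
        MapcodeRaster(
            out, 0, raster.origin_x, raster.origin_y, raster.cell_size_m, raster.crs_id
        ),
        table,
    )


def _block_mode(block: np.ndarray, nodata: int) -> int:
    vals, counts = np.unique(block[block != nodata], return_counts=True)
    if vals.size == 0:
        return nodata
    # np.unique sorts ascending and argmax takes the first maximum, so ties
    # resolve to the smallest value
    return int(vals[np.argmax(counts)])


def mode_aggregate(raster: MapcodeRaster, factor: int) -> MapcodeRaster:
    """Coarsen the grid by ``factor`` using the per-block mode.

    Each ``factor``×``factor`` block collapses to its most frequent
    non-nodata value (smallest value on ties); all-nodata blocks stay
    nodata.  Trailing partial blocks at the right/bottom edges aggregate
    over the cells they actually contain.  Factor 10 turns a 30 m grid into
    the 300 m product.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 2:
        raise ValueError(f"aggregation factor must be an integer >= 2, got {factor}")
    rows, cols = raster.grid.shape
    out_rows = -(-rows // factor)
    out_cols = -(-cols // factor)
    out = np.full((out_rows, out_cols), raster.nodata, dtype=np.int32)
    for i in range(out_rows):
        for j in range(out_cols):
            block = raster.grid[
                i * factor : (i + 1) * factor, j * factor : (j + 1) * factor
            ]
            out[i, j] = _block_mode(block, raster.nodata)
    return replace(
        raster,
        grid=out,
        cell_size_m=raster.cell_size_m * factor,
    )
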