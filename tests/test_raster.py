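"""Raster preparation: clipping, sequential remap, mode aggregation, GeoTIFF I/O."""

from collections import Counter

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon, box

from ricb.geotiff import read_geotiff, write_geotiff
from ricb.raster import (
    ClipError,
    GeometryError,
    MapcodeRaster,
    RemapTable,
    clip_to_aoi,
    mode_aggregate,
    remap_sequential,
)

CRS = "EPSG:32617"
NODATA = -1


def make_raster(grid, cell=30.0, ox=500_000.0, oy=3_900_000.0, nodata=NODATA):
    return MapcodeRaster(np.asarray(grid, dtype=np.int32), nodata, ox, oy, cell, CRS)


def full_footprint(raster):
    return box(*raster.bounds)


class TestClip:
    def test_identity_clip(self):
        r = make_raster(np.arange(1, 101).reshape(10, 10))
        out = clip_to_aoi(r, full_footprint(r), CRS)
        assert out == r

    def test_left_half_matches_center_rule_oracle(self):
        r = make_raster(np.arange(1, 101).reshape(10, 10))
        minx, miny, maxx, maxy = r.bounds
        half = box(minx, miny, (minx + maxx) / 2, maxy)
        out = clip_to_aoi(r, half, CRS)
        # brute-force oracle: count centers covered by the polygon
        xg, yg = r.cell_centers()
        want = int(shapely.intersects_xy(half, xg.ravel(), yg.ravel()).sum())
        assert want == 50
        assert int((out.grid != out.nodata).sum()) == want

    def test_idempotent(self):
        r = make_raster(np.arange(1, 101).reshape(10, 10))
        minx, miny, maxx, maxy = r.bounds
        aoi = Polygon(
            [
                (minx + 40, miny + 20),
                (maxx - 100, miny + 95),
                (maxx - 35, maxy - 60),
                (minx + 75, maxy - 20),
            ]
        )
        once = clip_to_aoi(r, aoi, CRS)
        twice = clip_to_aoi(once, aoi, CRS)
        assert once == twice

    def test_reprojects_aoi_not_raster(self):
        from ricb.crs import transform_points

        r = make_raster(np.full((10, 10), 3))
        minx, miny, maxx, maxy = r.bounds
        corners = [(minx, miny), (maxx, miny), (maxx, maxy), (minx, maxy)]
        lon, lat = transform_points(*zip(*corners), CRS, "EPSG:4326")
        out = clip_to_aoi(r, Polygon(zip(lon, lat)), "EPSG:4326")
        assert out.cell_size_m == r.cell_size_m  # grid untouched
        assert (out.grid != out.nodata).sum() >= 90  # nearly the full footprint

    def test_disjoint_aoi_errors(self):
        r = make_raster(np.full((5, 5), 2))
        far = box(0.0, 0.0, 10.0, 10.0)
        with pytest.raises(ClipError):
            clip_to_aoi(r, far, CRS)

    def test_corrupt_geometry_errors(self):
        r = make_raster(np.full((5, 5), 2))
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(GeometryError):
            clip_to_aoi(r, bowtie, CRS)


class TestRemap:
    def test_sorted_ascending_assignment(self):
        r = make_raster([[17, 4], [9, NODATA]])
        out, table = remap_sequential(r)
        assert table.to_sequential == {4: 1, 9: 2, 17: 3}
        assert out.grid.tolist() == [[3, 1], [2, 0]]
        assert out.nodata == 0

    def test_already_sequential_identity(self):
        r = make_raster([[1, 2], [3, 1]])
        _, table = remap_sequential(r)
        assert table.to_sequential == {1: 1, 2: 2, 3: 3}

    def test_inverse_composition_is_identity(self):
        rng = np.random.default_rng(0)
        grid = rng.choice([NODATA, 11, 407, 52_000], size=(12, 12))
        r = make_raster(grid)
        out, table = remap_sequential(r)
        restored = np.where(
            out.grid == 0,
            NODATA,
            np.vectorize(lambda v: table.to_original.get(v, NODATA))(out.grid),
        )
        assert np.array_equal(restored, grid)

    def test_all_nodata_errors(self):
        with pytest.raises(ClipError):
            remap_sequential(make_raster(np.full((3, 3), NODATA)))

    def test_remap_table_validates_bijection(self):
        with pytest.raises(ValueError):
            RemapTable({4: 1, 9: 3})  # codes not 1..K


class TestModeAggregate:
    def test_uniform_block(self):
        r = make_raster(np.full((4, 4), 7))
        out = mode_aggregate(r, 2)
        assert np.array_equal(out.grid, np.full((2, 2), 7))
        assert out.cell_size_m == 60.0

    def test_nodata_ignored_within_block(self):
        r = make_raster([[5, 5], [7, NODATA]])
        assert mode_aggregate(r, 2).grid.tolist() == [[5]]

    def test_tie_takes_smallest(self):
        r = make_raster([[3, 3], [9, 9]])
        assert mode_aggregate(r, 2).grid.tolist() == [[3]]

    def test_all_nodata_block_stays_nodata(self):
        r = make_raster([[NODATA, NODATA], [NODATA, 4]])
        out = mode_aggregate(make_raster(np.full((2, 2), NODATA)), 2)
        assert out.grid.tolist() == [[NODATA]]
        assert mode_aggregate(r, 2).grid.tolist() == [[4]]

    def test_partial_edge_blocks(self):
        r = make_raster([[1, 1, 2], [1, 1, 2], [5, 5, 5]])
        out = mode_aggregate(r, 2)
        assert out.grid.tolist() == [[1, 2], [5, 5]]

    def test_factor_below_two_rejected(self):
        r = make_raster(np.full((4, 4), 7))
        with pytest.raises(ValueError):
            mode_aggregate(r, 1)

    def test_matches_frequency_oracle_on_random_grids(self):
        rng = np.random.default_rng(1234)
        for trial in range(100):
            rows = int(rng.integers(2, 41))
            cols = int(rng.integers(2, 41))
            factor = int(rng.integers(2, 11))
            grid = rng.choice([NODATA, 1, 2, 3, 5, 8], size=(rows, cols))
            r = make_raster(grid)
            out = mode_aggregate(r, factor)
            assert out.grid.shape == (-(-rows // factor), -(-cols // factor))
            for i in range(out.grid.shape[0]):
                for j in range(out.grid.shape[1]):
                    block = grid[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
                    counts = Counter(v for v in block.ravel() if v != NODATA)
                    if not counts:
                        want = NODATA
                    else:
                        best = max(counts.values())
                        want = min(v for v, n in counts.items() if n == best)
                    assert out.grid[i, j] == want
            in_vals = set(np.unique(grid)) - {NODATA}
            out_vals = set(np.unique(out.grid)) - {NODATA}
            assert out_vals <= in_vals


class TestGeoTiff:
    def test_round_trip(self, tmp_path):
        r = make_raster(np.arange(1, 37).reshape(6, 6), cell=30.0)
        path = tmp_path / "m.tif"
        write_geotiff(r, path)
        back = read_geotiff(path)
        assert back == r

    def test_geographic_crs_round_trip(self, tmp_path):
        r = MapcodeRaster(
            np.array([[1, 2], [3, 0]], dtype=np.int32), 0, -81.0, 35.0, 0.001, "EPSG:4326"
        )
        path = tmp_path / "g.tif"
        write_geotiff(r, path)
        assert read_geotiff(path) == r

    def test_missing_georeferencing_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((4, 4), dtype=np.int32))
        with pytest.raises(ValueError):
            read_geotiff(path)
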