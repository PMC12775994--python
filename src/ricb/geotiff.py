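"""Single-band integer GeoTIFF reading and writing.

Implemented directly on :mod:`tifffile` with the standard GeoTIFF tags:
ModelPixelScale (33550) and ModelTiepoint (33922) carry the affine
georeferencing, the GeoKeyDirectory (34735) carries the EPSG code, and the
GDAL_NODATA ASCII tag (42113) carries the nodata value.  Only the north-up,
square-pixel, single-band integer layout the mapcode rasters use is
supported.
"""

from __future__ import annotations

import numpy as np
import tifffile

from .raster import MapcodeRaster

__all__ = ["read_geotiff", "write_geotiff"]

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS_TYPE = 3072

_MODEL_PROJECTED = 1
_MODEL_GEOGRAPHIC = 2
_RASTER_PIXEL_IS_AREA = 1


def _geokey_directory(crs_id: str) -> list[int]:
    epsg = int(crs_id.split(":")[1])
    if epsg == 4326:
        keys = [
            (_KEY_MODEL_TYPE, 0, 1, _MODEL_GEOGRAPHIC),
            (_KEY_RASTER_TYPE, 0, 1, _RASTER_PIXEL_IS_AREA),
            (_KEY_GEOGRAPHIC_TYPE, 0, 1, epsg),
        ]
    else:
        keys = [
            (_KEY_MODEL_TYPE, 0, 1, _MODEL_PROJECTED),
            (_KEY_RASTER_TYPE, 0, 1, _RASTER_PIXEL_IS_AREA),
            (_KEY_PROJECTED_CS_TYPE, 0, 1, epsg),
        ]
    directory = [1, 1, 0, len(keys)]
    for k in keys:
        directory.extend(k)
    return directory


def write_geotiff(raster: MapcodeRaster, path) -> None:
    """Write the raster as a single-band int32 GeoTIFF with nodata tag."""
    if not raster.crs_id:
        raise ValueError("raster has no CRS; refusing to write an unreferenced file")
    geokeys = tuple(_geokey_directory(raster.crs_id))
    nodata_ascii = str(raster.nodata)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (raster.cell_size_m, raster.cell_size_m, 0.0)),
        (
            _MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, raster.origin_x, raster.origin_y, 0.0),
        ),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii),
    ]
    tifffile.imwrite(
        str(path),
        raster.grid.astype(np.int32),
        photometric="minisblack",
        extratags=extratags,
    )


def _crs_from_geokeys(directory) -> str:
    vals = list(int(v) for v in np.atleast_1d(directory))
    keys = {}
    for i in range(4, len(vals) - 3, 4):
        key_id, location, _count, value = vals[i : i + 4]
        if location == 0:
            keys[key_id] = value
    if _KEY_PROJECTED_CS_TYPE in keys:
        return f"EPSG:{keys[_KEY_PROJECTED_CS_TYPE]}"
    if _KEY_GEOGRAPHIC_TYPE in keys:
        return f"EPSG:{keys[_KEY_GEOGRAPHIC_TYPE]}"
    raise ValueError("GeoTIFF GeoKey directory carries no EPSG CRS code")


def read_geotiff(path) -> MapcodeRaster:
    """Read a single-band integer GeoTIFF written by this package (or alike)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        grid = page.asarray()
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path} lacks GeoTIFF georeferencing tags")
        scale = tags[_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_MODEL_TIEPOINT].value
        if _GEO_KEY_DIRECTORY not in tags:
            raise ValueError(f"{path} lacks a GeoKey directory (no CRS)")
        crs_id = _crs_from_geokeys(tags[_GEO_KEY_DIRECTORY].value)
        nodata = 0
        if _GDAL_NODATA in tags:
            nodata = int(float(tags[_GDAL_NODATA].value))
    if grid.ndim != 2:
        raise ValueError(f"{path} is not single-band")
    if abs(scale[0] - scale[1]) > 1e-9:
        raise ValueError(f"{path} has non-square pixels: {scale[:2]}")
    i, j, _, x, y, _ = tiepoint[:6]
    origin_x = float(x) - float(j) * float(scale[0])
    origin_y = float(y) + float(i) * float(scale[1])
    return MapcodeRaster(
        grid.astype(np.int32), nodata, origin_x, origin_y, float(scale[0]), crs_id
    )
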