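"""Area-of-interest polygon readers and writers.

The AOI can arrive as GeoJSON, KML, or an ESRI shapefile.  GeoJSON and KML
carry geographic WGS84 coordinates by convention; a shapefile's CRS is read
from its ``.prj`` sidecar.  All readers return ``(shapely Polygon, crs_id)``
and raise :class:`~ricb.raster.GeometryError` for corrupt or non-polygonal
geometry.

The shapefile codec is a minimal, self-contained implementation of the ESRI
format (shape type 5, polygon) sufficient for AOI exchange: one polygon per
file, rings classified by area (largest ring is the shell, the rest holes).
"""

from __future__ import annotations

import json
import re
import struct
import xml.etree.ElementTree as ET
from pathlib import Path

from shapely.geometry import Polygon, shape
from shapely.geometry.polygon import orient

from .crs import normalize_crs, utm_zone_params
from .raster import GeometryError

__all__ = ["read_aoi", "write_geojson", "write_shapefile"]


def _validated(poly, crs_id: str) -> tuple[Polygon, str]:
    if poly.is_empty:
        raise GeometryError("AOI geometry is empty")
    if poly.geom_type == "MultiPolygon":
        parts = list(poly.geoms)
        if len(parts) != 1:
            raise GeometryError("AOI must be a single polygon")
        poly = parts[0]
    if poly.geom_type != "Polygon":
        raise GeometryError(f"AOI must be a polygon, got {poly.geom_type}")
    if not poly.is_valid:
        raise GeometryError("AOI geometry is corrupt (invalid polygon)")
    return poly, normalize_crs(crs_id)


# ---------------------------------------------------------------------------
# GeoJSON

def _geojson_crs(doc: dict) -> str:
    crs = doc.get("crs")
    if crs is None:
        return "EPSG:4326"
    name = crs.get("properties", {}).get("name", "")
    m = re.search(r"EPSG:?:?(\d+)", str(name))
    if not m:
        raise GeometryError(f"unparseable GeoJSON crs member: {name!r}")
    return f"EPSG:{m.group(1)}"


def _read_geojson(path: Path) -> tuple[Polygon, str]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GeometryError(f"{path} is not valid GeoJSON: {exc}") from exc
    crs_id = _geojson_crs(doc)
    kind = doc.get("type")
    if kind == "FeatureCollection":
        feats = doc.get("features", [])
        if not feats:
            raise GeometryError(f"{path} contains no features")
        geom = feats[0]["geometry"]
    elif kind == "Feature":
        geom = doc["geometry"]
    else:
        geom = doc
    try:
        poly = shape(geom)
    except Exception as exc:
        raise GeometryError(f"{path}: unreadable geometry: {exc}") from exc
    return _validated(poly, crs_id)


def write_geojson(poly: Polygon, crs_id: str, path) -> None:
    """Write the polygon as a one-feature GeoJSON FeatureCollection."""
    crs_id = normalize_crs(crs_id)
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": f"urn:ogc:def:crs:EPSG::{crs_id.split(':')[1]}"}},
        "features": [
            {
                "type": "Feature",
                "properties": {},
                "geometry": poly.__geo_interface__,
            }
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# KML

_KML_NS = "{http://www.opengis.net/kml/2.2}"


def _read_kml(path: Path) -> tuple[Polygon, str]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise GeometryError(f"{path} is not valid KML: {exc}") from exc
    rings = []
    for tag in ("outerBoundaryIs", "innerBoundaryIs"):
        for bound in tree.iter(f"{_KML_NS}{tag}"):
            coords_el = bound.find(f".//{_KML_NS}coordinates")
            if coords_el is None or not coords_el.text:
                raise GeometryError(f"{path}: KML ring without coordinates")
            pts = []
            for token in coords_el.text.split():
                parts = token.split(",")
                pts.append((float(parts[0]), float(parts[1])))
            rings.append((tag == "outerBoundaryIs", pts))
    outers = [pts for outer, pts in rings if outer]
    inners = [pts for outer, pts in rings if not outer]
    if len(outers) != 1:
        raise GeometryError(f"{path}: expected exactly one KML outer ring, got {len(outers)}")
    return _validated(Polygon(outers[0], inners), "EPSG:4326")


# ---------------------------------------------------------------------------
# ESRI shapefile (shape type 5)

_SHAPE_POLYGON = 5


def _ring_area(pts) -> float:
    s = 0.0
    for (x1, y1), (x2, y2) in zip(pts, pts[1:]):
        s += x1 * y2 - x2 * y1
    return s / 2.0


def _read_shp(path: Path) -> Polygon:
    data = path.read_bytes()
    if len(data) < 100:
        raise GeometryError(f"{path}: truncated shapefile")
    (file_code,) = struct.unpack(">i", data[:4])
    if file_code != 9994:
        raise GeometryError(f"{path}: bad shapefile magic {file_code}")
    (shape_type,) = struct.unpack("<i", data[32:36])
    if shape_type != _SHAPE_POLYGON:
        raise GeometryError(f"{path}: shape type {shape_type} is not polygon")
    offset = 100
    if offset + 8 > len(data):
        raise GeometryError(f"{path}: shapefile has no records")
    (_recno, content_len) = struct.unpack(">ii", data[offset : offset + 8])
    rec = data[offset + 8 : offset + 8 + 2 * content_len]
    (rec_type,) = struct.unpack("<i", rec[:4])
    if rec_type != _SHAPE_POLYGON:
        raise GeometryError(f"{path}: record shape type {rec_type} is not polygon")
    num_parts, num_points = struct.unpack("<ii", rec[36:44])
    parts = struct.unpack(f"<{num_parts}i", rec[44 : 44 + 4 * num_parts])
    pts_raw = struct.unpack(
        f"<{2 * num_points}d",
        rec[44 + 4 * num_parts : 44 + 4 * num_parts + 16 * num_points],
    )
    pts = list(zip(pts_raw[0::2], pts_raw[1::2]))
    bounds = list(parts) + [num_points]
    rings = [pts[bounds[i] : bounds[i + 1]] for i in range(num_parts)]
    if not rings:
        raise GeometryError(f"{path}: polygon record with no rings")
    rings.sort(key=lambda r: abs(_ring_area(r)), reverse=True)
    return Polygon(rings[0], rings[1:])


def _read_prj(path: Path) -> str:
    if not path.exists():
        return "EPSG:4326"
    wkt = path.read_text()
    m = re.search(r"UTM[_ ]Zone[_ ](\d+)([NS])", wkt, flags=re.IGNORECASE)
    if m:
        zone = int(m.group(1))
        base = 32600 if m.group(2).upper() == "N" else 32700
        return f"EPSG:{base + zone}"
    if re.search(r"GEOGCS", wkt) and re.search(r"WGS[_ ]?(19)?84", wkt):
        return "EPSG:4326"
    raise GeometryError(f"{path}: unrecognized projection WKT")


def _read_shapefile(path: Path) -> tuple[Polygon, str]:
    poly = _read_shp(path)
    crs_id = _read_prj(path.with_suffix(".prj"))
    return _validated(poly, crs_id)


def _prj_wkt(crs_id: str) -> str:
    geogcs = (
        'GEOGCS["GCS_WGS_1984",DATUM["D_WGS_1984",'
        'SPHEROID["WGS_1984",6378137.0,298.257223563]],'
        'PRIMEM["Greenwich",0.0],UNIT["Degree",0.0174532925199433]]'
    )
    crs_id = normalize_crs(crs_id)
    if crs_id == "EPSG:4326":
        return geogcs
    epsg = int(crs_id.split(":")[1])
    zone = epsg % 100
    hemi = "N" if 32600 < epsg < 32661 else "S"
    lon0, fe, fn = utm_zone_params(crs_id)
    return (
        f'PROJCS["WGS_1984_UTM_Zone_{zone}{hemi}",{geogcs},'
        'PROJECTION["Transverse_Mercator"],'
        f'PARAMETER["False_Easting",{fe}],PARAMETER["False_Northing",{fn}],'
        f'PARAMETER["Central_Meridian",{lon0}],PARAMETER["Scale_Factor",0.9996],'
        'PARAMETER["Latitude_Of_Origin",0.0],UNIT["Meter",1.0]]'
    )


def write_shapefile(poly: Polygon, crs_id: str, path) -> None:
    """Write a single-polygon ESRI shapefile (.shp + .shx + .dbf + .prj)."""
    path = Path(path)
    poly = orient(poly, sign=-1.0)  # shapefile convention: shell clockwise
    rings = [list(poly.exterior.coords)] + [
        list(orient(Polygon(i), sign=1.0).exterior.coords) for i in poly.interiors
    ]
    xs = [x for ring in rings for x, _ in ring]
    ys = [y for ring in rings for _, y in ring]
    bbox = (min(xs), min(ys), max(xs), max(ys))

    num_points = sum(len(r) for r in rings)
    parts = []
    acc = 0
    for r in rings:
        parts.append(acc)
        acc += len(r)
    content = struct.pack("<i", _SHAPE_POLYGON)
    content += struct.pack("<4d", *bbox)
    content += struct.pack("<ii", len(rings), num_points)
    content += struct.pack(f"<{len(parts)}i", *parts)
    for r in rings:
        for x, y in r:
            content += struct.pack("<2d", x, y)

    def header(total_bytes: int) -> bytes:
        h = struct.pack(">i", 9994) + b"\x00" * 20
        h += struct.pack(">i", total_bytes // 2)
        h += struct.pack("<ii", 1000, _SHAPE_POLYGON)
        h += struct.pack("<4d", *bbox)
        h += struct.pack("<4d", 0, 0, 0, 0)
        return h

    rec_header = struct.pack(">ii", 1, len(content) // 2)
    path.with_suffix(".shp").write_bytes(
        header(100 + 8 + len(content)) + rec_header + content
    )
    shx_rec = struct.pack(">ii", 50, len(content) // 2)
    path.with_suffix(".shx").write_bytes(header(100 + 8) + shx_rec)
    path.with_suffix(".prj").write_text(_prj_wkt(crs_id))

    # minimal dBASE sidecar: one numeric ID field, one record
    field = b"ID".ljust(11, b"\x00") + b"N" + b"\x00" * 4 + bytes([10, 0]) + b"\x00" * 14
    dbf_header = struct.pack(
        "<BBBBIHH", 3, 26, 1, 1, 1, 32 + 32 + 1, 1 + 10
    ) + b"\x00" * 20
    record = b" " + b"1".rjust(10)
    path.with_suffix(".dbf").write_bytes(dbf_header + field + b"\x0d" + record + b"\x1a")


# ---------------------------------------------------------------------------

_READERS = {
    ".geojson": _read_geojson,
    ".json": _read_geojson,
    ".kml": _read_kml,
    ".shp": _read_shapefile,
}


def read_aoi(path) -> tuple[Polygon, str]:
    """Read an AOI polygon from GeoJSON, KML, or shapefile.

    Returns the polygon and its CRS identifier.  The format is chosen by
    file extension.
    """
    path = Path(path)
    reader = _READERS.get(path.suffix.lower())
    if reader is None:
        raise GeometryError(
            f"unsupported AOI format {path.suffix!r}; use .geojson/.json, .kml, or .shp"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    return reader(path)
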