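"""Minimal coordinate-reference-system support.

The pipeline only ever reprojects the user's area-of-interest polygon into
the CRS of the mapcode raster (the raster grid itself is never resampled).
The rasters this tool targets are published in UTM zones or geographic
WGS84, so the supported CRSs are:

* ``EPSG:4326``  — geographic WGS84 (longitude/latitude degrees)
* ``EPSG:326zz`` — WGS84 / UTM zone ``zz`` north
* ``EPSG:327zz`` — WGS84 / UTM zone ``zz`` south

Transforms use the ellipsoidal Transverse Mercator series (Snyder 1987,
eqs. 8-9..8-25), accurate to well under a millimetre within a UTM zone.
"""

from __future__ import annotations

import math
import re
from typing import Iterable

import numpy as np

__all__ = ["normalize_crs", "same_crs", "transform_points", "utm_zone_params"]

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996

_UTM_RE = re.compile(r"^EPSG:32([67])(\d{2})$")


def normalize_crs(crs_id: str) -> str:
    """Canonicalize a CRS identifier to ``EPSG:nnnn`` form.

    Accepts ``epsg:4326``, ``EPSG:32617`` etc.  Raises ``ValueError`` for
    identifiers outside the supported set.
    """
    if not isinstance(crs_id, str) or ":" not in crs_id:
        raise ValueError(f"unsupported CRS identifier: {crs_id!r}")
    auth, _, code = crs_id.partition(":")
    norm = f"{auth.upper()}:{code}"
    if norm == "EPSG:4326" or _UTM_RE.match(norm):
        return norm
    raise ValueError(
        f"unsupported CRS {crs_id!r}: supported are EPSG:4326 and WGS84 UTM "
        "(EPSG:326xx / EPSG:327xx)"
    )


def same_crs(a: str, b: str) -> bool:
    return normalize_crs(a) == normalize_crs(b)


def utm_zone_params(crs_id: str) -> tuple[float, float, float]:
    """Return (central meridian deg, false easting m, false northing m)."""
    m = _UTM_RE.match(normalize_crs(crs_id))
    if m is None:
        raise ValueError(f"{crs_id!r} is not a UTM CRS")
    hemi, zone = m.group(1), int(m.group(2))
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone {zone} out of range 1..60")
    lon0 = -183.0 + 6.0 * zone
    fn = 0.0 if hemi == "6" else 10_000_000.0
    return lon0, 500_000.0, fn


def _meridian_arc(phi: np.ndarray) -> np.ndarray:
    e2, e4, e6 = _E2, _E2**2, _E2**3
    return _A * (
        (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * np.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * np.sin(4 * phi)
        - (35 * e6 / 3072) * np.sin(6 * phi)
    )


def _geographic_to_utm(lon, lat, crs_id):
    lon0_deg, fe, fn = utm_zone_params(crs_id)
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    lam0 = math.radians(lon0_deg)

    n = _A / np.sqrt(1 - _E2 * np.sin(phi) ** 2)
    t = np.tan(phi) ** 2
    c = _EP2 * np.cos(phi) ** 2
    a = (lam - lam0) * np.cos(phi)
    m = _meridian_arc(phi)

    x = fe + _K0 * n * (
        a
        + (1 - t + c) * a**3 / 6
        + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a**5 / 120
    )
    y = fn + _K0 * (
        m
        + n
        * np.tan(phi)
        * (
            a**2 / 2
            + (5 - t + 9 * c + 4 * c**2) * a**4 / 24
            + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a**6 / 720
        )
    )
    return x, y


def _utm_to_geographic(x, y, crs_id):
    lon0_deg, fe, fn = utm_zone_params(crs_id)
    x = np.asarray(x, dtype=float) - fe
    y = np.asarray(y, dtype=float) - fn
    lam0 = math.radians(lon0_deg)

    m = y / _K0
    mu = m / (_A * (1 - _E2 / 4 - 3 * _E2**2 / 64 - 5 * _E2**3 / 256))
    e1 = (1 - math.sqrt(1 - _E2)) / (1 + math.sqrt(1 - _E2))
    phi1 = (
        mu
        + (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
        + (151 * e1**3 / 96) * np.sin(6 * mu)
        + (1097 * e1**4 / 512) * np.sin(8 * mu)
    )

    c1 = _EP2 * np.cos(phi1) ** 2
    t1 = np.tan(phi1) ** 2
    n1 = _A / np.sqrt(1 - _E2 * np.sin(phi1) ** 2)
    r1 = _A * (1 - _E2) / (1 - _E2 * np.sin(phi1) ** 2) ** 1.5
    d = x / (n1 * _K0)

    phi = phi1 - (n1 * np.tan(phi1) / r1) * (
        d**2 / 2
        - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24
        + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2 - 3 * c1**2)
        * d**6
        / 720
    )
    lam = lam0 + (
        d
        - (1 + 2 * t1 + c1) * d**3 / 6
        + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2 + 24 * t1**2) * d**5 / 120
    ) / np.cos(phi1)
    return np.degrees(lam), np.degrees(phi)


def transform_points(
    xs: Iterable[float], ys: Iterable[float], src_crs: str, dst_crs: str
) -> tuple[np.ndarray, np.ndarray]:
    """Transform coordinate arrays from ``src_crs`` to ``dst_crs``.

    Geographic coordinates are (longitude, latitude) in degrees; projected
    coordinates are (easting, northing) in metres.  UTM-to-UTM transforms
    route through geographic WGS84.
    """
    src, dst = normalize_crs(src_crs), normalize_crs(dst_crs)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if src == dst:
        return xs.copy(), ys.copy()
    if src == "EPSG:4326":
        return _geographic_to_utm(xs, ys, dst)
    if dst == "EPSG:4326":
        return _utm_to_geographic(xs, ys, src)
    lon, lat = _utm_to_geographic(xs, ys, src)
    return _geographic_to_utm(lon, lat, dst)
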