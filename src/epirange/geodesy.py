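"""Spherical-geometry helpers shared by the cleaning and range-metric modules.

All computations use a sphere of authalic radius 6371.0072 km, so that
polygon areas are directly comparable to areas on the WGS84 ellipsoid.
"""

from __future__ import annotations

import math

import numpy as np

#: Authalic (equal-area) sphere radius, km.
EARTH_RADIUS_KM = 6371.0072
EARTH_RADIUS_M = EARTH_RADIUS_KM * 1000.0
#: Length of one degree of latitude on the authalic sphere, km.
KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters between two WGS84 points."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def spherical_polygon_area_km2(lats_deg, lons_deg) -> float:
    """Area (km^2) of a polygon on the authalic sphere.

    Vertices are given in order (either orientation, not closed). Uses the
    Chamberlain–Duquette line-integral formula, which is exact for edges
    running along meridians and parallels and accurate to well below 0.1%
    for the small-extent convex polygons this package produces.
    """
    lam = np.radians(np.asarray(lons_deg, dtype=float))
    phi = np.radians(np.asarray(lats_deg, dtype=float))
    if lam.size < 3:
        raise ValueError("polygon needs at least 3 vertices")
    lam2 = np.roll(lam, -1)
    phi2 = np.roll(phi, -1)
    total = np.sum((lam2 - lam) * (2.0 + np.sin(phi) + np.sin(phi2)))
    return float(abs(total) * EARTH_RADIUS_KM**2 / 2.0)


def grid_cell(lat: float, lon: float, cell_m: float) -> tuple[int, int]:
    """Index of the square grid cell containing a point.

    The point is projected equirectangularly at its own latitude (x scaled
    by cos(lat)), then binned into ``cell_m``-sized cells.
    """
    y = math.radians(lat) * EARTH_RADIUS_M
    x = math.radians(lon) * EARTH_RADIUS_M * math.cos(math.radians(lat))
    return (math.floor(x / cell_m), math.floor(y / cell_m))
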