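"""Planar geometry on a spherical Earth.

All analysis-side geometry is done in meters, in a local azimuthal-equidistant
(AEQD) frame centered on a per-user origin.  AEQD preserves both distance and
bearing *from the origin* exactly, which is the quantity the mobility
statistics (distance from expected location, gyradius) are built on.  A
spherical Earth of radius 6,371 km is used throughout; ellipsoidal corrections
are far below the ~10 m GPS noise floor of the data this package targets.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "haversine_m",
    "project_local",
    "unproject_local",
]


def haversine_m(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_M):
    """Great-circle distance in meters between (lat1, lon1) and (lat2, lon2).

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    phi1, lam1, phi2, lam2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def project_local(lat, lon, origin_lat: float, origin_lon: float):
    """Project lat/lon (degrees) to planar (x east, y north) meters about an origin.

    Spherical azimuthal-equidistant projection: the planar distance of every
    point from the origin equals its great-circle distance.

    Raises
    ------
    ValueError
        If any point is within 1 km of the origin's antipode, where the
        projection is singular.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    phi = np.radians(lat)
    lam = np.radians(lon)
    phi0 = np.radians(origin_lat)
    lam0 = np.radians(origin_lon)

    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    if np.any(c > np.pi - 1e-3):
        # within ~6 km of the antipode the projection is singular
        raise ValueError("point at or near the antipode of the projection origin")
    # k = c / sin(c), with the removable singularity at c = 0
    sin_c = np.sin(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(sin_c > 0.0, c / np.where(sin_c > 0.0, sin_c, 1.0), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def unproject_local(x, y, origin_lat: float, origin_lon: float):
    """Inverse of :func:`project_local`; returns (lat, lon) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    phi0 = np.radians(origin_lat)
    lam0 = np.radians(origin_lon)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_M
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_rho = np.where(rho > 0.0, rho, 1.0)
        phi = np.where(
            rho > 0.0,
            np.arcsin(np.clip(np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / safe_rho, -1.0, 1.0)),
            phi0,
        )
        lam = np.where(
            rho > 0.0,
            lam0
            + np.arctan2(
                x * np.sin(c),
                safe_rho * np.cos(c) * np.cos(phi0) - y * np.sin(c) * np.sin(phi0),
            ),
            lam0,
        )
    lat = np.degrees(phi)
    lon = np.degrees(lam)
    # wrap longitude into [-180, 180]
    lon = (lon + 180.0) % 360.0 - 180.0
    return lat, lon
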