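"""Map projection and distance primitives.

Telemetry fixes arrive as geographic longitude/latitude; everything
downstream (movement modelling, the 10-km analysis grid) works in planar
metres. We use an oblique Mercator projection centred on 35.0°N, 75.0°W —
the conventional choice for the US northeast shelf — realised as a Mercator
projection on a rotated sphere so the centre maps to the origin and local
scale error stays below 0.1% over the study region.

A spherical earth (mean radius 6371.0088 km) is used throughout; at the
scale of a 10-km grid the spheroidal correction is irrelevant.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8

#: Projection centre: 35.0°N, 75.0°W.
CENTER_LON = -75.0
CENTER_LAT = 35.0


def _rotation_matrix(lon0: float, lat0: float) -> np.ndarray:
    """Rotation taking the unit vector at (lon0, lat0) to (1, 0, 0)."""
    lam, phi = np.radians(lon0), np.radians(lat0)
    rz = np.array(
        [
            [np.cos(lam), np.sin(lam), 0.0],
            [-np.sin(lam), np.cos(lam), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    ry = np.array(
        [
            [np.cos(phi), 0.0, np.sin(phi)],
            [0.0, 1.0, 0.0],
            [-np.sin(phi), 0.0, np.cos(phi)],
        ]
    )
    return ry @ rz


def project_coordinates(
    lon, lat, *, lon0: float = CENTER_LON, lat0: float = CENTER_LAT
):
    """Forward oblique-Mercator projection: (lon, lat) degrees -> (x, y) metres.

    The projection centre maps exactly to (0, 0). Points whose rotated
    latitude approaches ±90° (the rotated poles, e.g. the antipode of the
    centre meridian) are rejected because the Mercator ordinate diverges
    there.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    lam, phi = np.radians(lon), np.radians(lat)
    v = np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)],
        axis=-1,
    )
    r = _rotation_matrix(lon0, lat0)
    vr = v @ r.T
    lat_r = np.arcsin(np.clip(vr[..., 2], -1.0, 1.0))
    lon_r = np.arctan2(vr[..., 1], vr[..., 0])
    if np.any(np.abs(lat_r) > np.radians(89.0)):
        raise ValueError(
            "point too close to the rotated pole of the oblique projection"
        )
    x = EARTH_RADIUS_M * lon_r
    y = EARTH_RADIUS_M * np.log(np.tan(np.pi / 4.0 + lat_r / 2.0))
    return x, y


def unproject_coordinates(
    x, y, *, lon0: float = CENTER_LON, lat0: float = CENTER_LAT
):
    """Inverse of :func:`project_coordinates`: (x, y) metres -> (lon, lat)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon_r = x / EARTH_RADIUS_M
    lat_r = 2.0 * np.arctan(np.exp(y / EARTH_RADIUS_M)) - np.pi / 2.0
    v = np.stack(
        [
            np.cos(lat_r) * np.cos(lon_r),
            np.cos(lat_r) * np.sin(lon_r),
            np.sin(lat_r),
        ],
        axis=-1,
    )
    r = _rotation_matrix(lon0, lat0)
    vi = v @ r  # R is orthogonal: inverse = transpose, applied as v @ R
    lat = np.degrees(np.arcsin(np.clip(vi[..., 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(vi[..., 1], vi[..., 0]))
    return lon, lat


def great_circle_distance_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres (haversine, spherical earth)."""
    lam1, phi1 = np.radians(lon1), np.radians(lat1)
    lam2, phi2 = np.radians(lon2), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    )
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
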