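"""Spherical geometry: equal-area projection and great-circle helpers.

All planar work in this package happens in a Lambert azimuthal equal-area
projection centred on the study region (the same family of projection used
for pan-European tracking analyses). The spherical form is used with the
mean Earth radius; round-trip error is far below GPS accuracy, and the
equal-area property — the only one the gridded utilization distributions
rely on — holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0
EARTH_RADIUS_M = EARTH_RADIUS_KM * 1000.0


@dataclass(frozen=True)
class ProjectionSpec:
    """Lambert azimuthal equal-area projection centred at (lon_0, lat_0)."""

    lon_0: float
    lat_0: float

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to planar x/y in metres.

        The projection centre maps to (0, 0).
        """
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        lam0 = np.radians(self.lon_0)
        phi0 = np.radians(self.lat_0)
        dlam = lam - lam0
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
        if np.any(denom <= 1e-12):
            bad = np.nonzero(np.atleast_1d(denom) <= 1e-12)[0]
            raise ValueError(
                f"projection undefined (antipode of centre) for point index {bad[0]}"
            )
        k = np.sqrt(2.0 / denom)
        x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_M * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y):
        """Inverse projection: planar metres back to lon/lat degrees."""
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_M
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_M
        phi0 = np.radians(self.lat_0)
        lam0 = np.radians(self.lon_0)
        rho = np.hypot(x, y)
        # 2*arcsin(rho/2) is the angular distance from the centre
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho > 0,
                np.arcsin(
                    np.clip(
                        np.cos(c) * np.sin(phi0) + (y * np.sin(c) * np.cos(phi0)) / np.where(rho > 0, rho, 1.0),
                        -1.0,
                        1.0,
                    )
                ),
                phi0,
            )
            lam = np.where(
                rho > 0,
                lam0
                + np.arctan2(
                    x * np.sin(c),
                    rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
                ),
                lam0,
            )
        return np.degrees(lam), np.degrees(phi)


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _to_unit(lon, lat):
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)], axis=-1
    )


def _from_unit(v):
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1, 1)))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lon, lat


def destination(lon, lat, bearing_deg, distance_km):
    """Point reached travelling `distance_km` along `bearing_deg` from start."""
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    theta = np.radians(bearing_deg)
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return np.degrees(lam2), np.degrees(phi2)


def gc_interpolate(lon1, lat1, lon2, lat2, fractions, lateral_offset_km=None):
    """Great-circle interpolation with optional perpendicular offset.

    Parameters
    ----------
    fractions : array of values in [0, 1], position along the arc.
    lateral_offset_km : optional array (same shape) of signed perpendicular
        displacements; positive offsets are to the left of the direction of
        travel. Used by the synthetic generator to curve migration corridors.
    """
    f = np.asarray(fractions, dtype=float)
    a = _to_unit(lon1, lat1)
    b = _to_unit(lon2, lat2)
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    if omega < 1e-12:
        pts = np.broadcast_to(a, f.shape + (3,)).copy()
    else:
        s = np.sin(omega)
        pts = (
            np.sin((1 - f)[:, None] * omega) * a[None, :]
            + np.sin(f[:, None] * omega) * b[None, :]
        ) / s
    if lateral_offset_km is not None:
        off = np.asarray(lateral_offset_km, dtype=float) / EARTH_RADIUS_KM
        normal = np.cross(a, b)
        nrm = np.linalg.norm(normal)
        if nrm > 1e-12:
            normal = normal / nrm
            pts = np.cos(off)[:, None] * pts + np.sin(off)[:, None] * normal[None, :]
    return _from_unit(pts)
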