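"""Colony-centred planar projection and great-circle bearings.

Tracks span a few tens of kilometres around a single colony, so a local
azimuthal-equidistant projection on the sphere is used: distances and
bearings *from the projection centre* are exact, the inverse is closed
form, and there are no zone boundaries to worry about.  Planar distances
between arbitrary nearby points are accurate to well under 0.1 % at the
scales involved (< 100 km).
"""

from __future__ import annotations

import numpy as np

#: mean Earth radius, metres (IUGG)
EARTH_RADIUS_M = 6_371_008.8


class LocalProjection:
    """Azimuthal-equidistant projection centred on a reference lon/lat.

    ``forward`` maps WGS84-style geographic coordinates (decimal degrees)
    to planar metres with the reference at (0, 0), x east, y north;
    ``inverse`` is its exact inverse (round-trip error is pure floating
    point, far below 1 m).
    """

    def __init__(self, lon0: float, lat0: float, radius: float = EARTH_RADIUS_M):
        if not (-180.0 <= lon0 <= 180.0 and -90.0 <= lat0 <= 90.0):
            raise ValueError(f"reference ({lon0}, {lat0}) is not a valid lon/lat")
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.radius = float(radius)
        self._lam0 = np.radians(lon0)
        self._phi0 = np.radians(lat0)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        cos_c = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), with limit 1 at c -> 0
        sin_c = np.sin(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(sin_c > 1e-12, c / np.where(sin_c > 1e-12, sin_c, 1.0), 1.0)
        x = self.radius * k * np.cos(phi) * np.sin(dlam)
        y = self.radius * k * (np.cos(self._phi0) * np.sin(phi)
                               - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        c = rho / self.radius
        sin_c, cos_c = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            safe_rho = np.where(rho > 1e-9, rho, 1.0)
            phi = np.arcsin(np.clip(
                cos_c * np.sin(self._phi0) + (y * sin_c * np.cos(self._phi0)) / safe_rho,
                -1.0, 1.0))
            lam = self._lam0 + np.arctan2(
                x * sin_c,
                safe_rho * cos_c * np.cos(self._phi0) - y * sin_c * np.sin(self._phi0))
        phi = np.where(rho > 1e-9, phi, self._phi0)
        lam = np.where(rho > 1e-9, lam, self._lam0)
        return np.degrees(lam), np.degrees(phi)


def initial_bearing(lon0: float, lat0: float, lon, lat):
    """Initial great-circle bearing from (lon0, lat0) to point(s), degrees.

    Clockwise from true north, mapped to (-180, 180] so that due south is
    +180 (never -180).  A point coincident with the origin has no defined
    bearing and yields NaN.
    """
    phi0 = np.radians(lat0)
    phi = np.radians(np.asarray(lat, dtype=float))
    dlam = np.radians(np.asarray(lon, dtype=float) - lon0)
    yy = np.sin(dlam) * np.cos(phi)
    xx = np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
    theta = np.degrees(np.arctan2(yy, xx))
    # atan2 returns (-180, 180]; force the -180 branch to +180
    theta = np.where(np.isclose(theta, -180.0), 180.0, theta)
    coincident = (yy == 0) & (xx == 0)
    theta = np.where(coincident, np.nan, theta)
    if np.ndim(lon) == 0 and np.ndim(lat) == 0:
        return float(theta)
    return theta


def planar_bearing(x, y):
    """Bearing of planar point(s) as seen from the origin, degrees in (-180, 180]."""
    theta = np.degrees(np.arctan2(np.asarray(x, float), np.asarray(y, float)))
    theta = np.where(np.isclose(theta, -180.0), 180.0, theta)
    theta = np.where((np.asarray(x) == 0) & (np.asarray(y) == 0), np.nan, theta)
    if np.ndim(x) == 0 and np.ndim(y) == 0:
        return float(theta)
    return theta
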