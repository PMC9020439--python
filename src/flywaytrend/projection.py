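"""Equal-area map projection used for metric gridding.

Survey coordinates arrive as WGS84 longitude/latitude; the 75-km grid
standardization needs planar coordinates in meters.  We use the Lambert
azimuthal equal-area projection on the authalic sphere, centered by default
at 52°N 10°E (the anchor of the pan-European ETRS-LAEA grid), which keeps
area — and hence grid-cell footprint — constant across the domain.  Forward
and inverse transforms are closed-form, so round-tripping is exact to
floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Authalic Earth radius in meters (sphere with the same surface area as WGS84).
EARTH_RADIUS_M = 6_371_007.181


@dataclass(frozen=True)
class LambertAzimuthalEqualArea:
    """Spherical Lambert azimuthal equal-area projection.

    Parameters
    ----------
    lon0, lat0:
        Projection center in degrees. Defaults match the European LAEA grid.
    radius:
        Sphere radius in meters.
    """

    lon0: float = 10.0
    lat0: float = 52.0
    radius: float = EARTH_RADIUS_M

    def forward(self, lon, lat):
        """Project lon/lat degrees to planar x/y meters."""
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(2.0 / denom)
        x = self.radius * k * np.cos(phi) * np.sin(lam)
        y = self.radius * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        """Unproject planar x/y meters back to lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        phi0 = np.radians(self.lat0)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / (2.0 * self.radius), -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.arcsin(np.clip(
                np.cos(c) * np.sin(phi0) + np.where(rho > 0, y * np.sin(c) * np.cos(phi0) / rho, 0.0),
                -1.0, 1.0))
            lam = np.arctan2(
                x * np.sin(c),
                rho * np.cos(c) * np.cos(phi0) - y * np.sin(c) * np.sin(phi0),
            )
        lam = np.where(rho > 0, lam, 0.0)
        phi = np.where(rho > 0, phi, phi0)
        return self.lon0 + np.degrees(lam), np.degrees(phi)


#: Registry of named coordinate reference systems accepted by the pipeline.
NAMED_CRS = {
    "laea-europe": LambertAzimuthalEqualArea(),
}


def get_projection(crs: str | LambertAzimuthalEqualArea) -> LambertAzimuthalEqualArea:
    """Resolve a CRS identifier to a projection object.

    Raises
    ------
    KeyError
        If the identifier is unknown (configuration error).
    """
    if isinstance(crs, LambertAzimuthalEqualArea):
        return crs
    try:
        return NAMED_CRS[crs]
    except KeyError:
        raise KeyError(
            f"unknown CRS {crs!r}; known identifiers: {sorted(NAMED_CRS)}"
        ) from None


def great_circle_distance(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS_M):
    """Haversine distance in meters on the authalic sphere."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(a))
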