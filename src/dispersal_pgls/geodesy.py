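"""Ellipsoidal geodesic distances.

Dispersal and migration distances are great-ellipse ("Vincenty") geodesic
distances on the WGS84 ellipsoid, the standard choice for shortest distances
between geographic coordinates.  Only the inverse problem (two points ->
distance) is implemented; azimuths and the forward problem are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GeoPoint",
    "Ellipsoid",
    "WGS84",
    "VincentyNonConvergence",
    "vincenty_distance",
]


class VincentyNonConvergence(RuntimeError):
    """Raised when the inverse iteration fails to converge.

    This happens only for nearly antipodal point pairs, which are far outside
    the distance regime of within-range dispersal movements.  The caller
    decides on a fallback; no silent substitution is performed.
    """

    def __init__(self, p: "GeoPoint", q: "GeoPoint") -> None:
        super().__init__(
            f"Vincenty inverse iteration did not converge for the "
            f"near-antipodal pair {p} and {q}"
        )
        self.p = p
        self.q = q


def _normalize_lon(lon: float) -> float:
    # map to (-180, 180]
    lon = math.fmod(lon, 360.0)
    if lon <= -180.0:
        lon += 360.0
    elif lon > 180.0:
        lon -= 360.0
    return lon


@dataclass(frozen=True)
class GeoPoint:
    """A geographic coordinate in decimal degrees.

    Latitude must lie in [-90, 90]; longitude is normalized to (-180, 180]
    on construction, so e.g. ``GeoPoint(0, 190)`` equals ``GeoPoint(0, -170)``.
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValueError(f"non-finite coordinates ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", _normalize_lon(float(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.lat}, {self.lon})"


@dataclass(frozen=True)
class Ellipsoid:
    """Reference ellipsoid: equatorial radius ``a`` (m) and flattening ``f``."""

    a: float = 6378137.0
    f: float = 1.0 / 298.257223563

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("equatorial radius must be positive")
        if not 0.0 <= self.f < 1.0:
            raise ValueError("flattening must lie in [0, 1)")

    @property
    def b(self) -> float:
        """Polar semi-minor axis in meters."""
        return self.a * (1.0 - self.f)


WGS84 = Ellipsoid()

#: convergence tolerance on the lambda iteration (radians)
_LAMBDA_TOL = 1e-12
_MAX_ITER = 200


def vincenty_distance(p: GeoPoint, q: GeoPoint, ellipsoid: Ellipsoid = WGS84) -> float:
    """Inverse geodesic distance between two points, in kilometers.

    Implements Vincenty's inverse iteration with a tolerance of 1e-12 on the
    longitude-difference iterate and at most 200 iterations.  The result is
    symmetric in its arguments and exactly zero for coincident points.

    Raises
    ------
    VincentyNonConvergence
        For nearly antipodal pairs, where the classical iteration stalls.
    """
    if p.lat == q.lat and p.lon == q.lon:
        return 0.0

    a, f, b = ellipsoid.a, ellipsoid.f, ellipsoid.b

    phi1, phi2 = math.radians(p.lat), math.radians(q.lat)
    L = math.radians(_normalize_lon(q.lon - p.lon))

    U1 = math.atan((1.0 - f) * math.tan(phi1))
    U2 = math.atan((1.0 - f) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(_MAX_ITER):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0  # coincident after reduction
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos_sq_alpha = 1.0 - sin_alpha * sin_alpha
        if cos_sq_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial geodesic
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos_sq_alpha
        C = f / 16.0 * cos_sq_alpha * (4.0 + f * (4.0 - 3.0 * cos_sq_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * f * sin_alpha * (
            sigma
            + C
            * sin_sigma
            * (cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < _LAMBDA_TOL:
            break
    else:
        raise VincentyNonConvergence(p, q)

    u_sq = cos_sq_alpha * (a * a - b * b) / (b * b)
    A = 1.0 + u_sq / 16384.0 * (
        4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq))
    )
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
                - B
                / 6.0
                * cos_2sigma_m
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos_2sigma_m**2)
            )
        )
    )
    return b * A * (sigma - delta_sigma) / 1000.0


def haversine_distance(p: GeoPoint, q: GeoPoint, radius_km: float = 6371.0) -> float:
    """Great-circle distance on a sphere, in km.  Used only as a sanity check."""
    phi1, phi2 = math.radians(p.lat), math.radians(q.lat)
    dphi = phi2 - phi1
    dlam = math.radians(_normalize_lon(q.lon - p.lon))
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(h)))
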