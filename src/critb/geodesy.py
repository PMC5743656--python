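"""Coordinate, distance, projection and area primitives.

All range metrics (EOO, AOO, locations, subpopulations) are km-denominated
quantities derived from WGS84 decimal-degree coordinates.  This module fixes
one earth model — a sphere of authalic radius — and one planar frame — a
Lambert azimuthal equal-area (LAEA) projection centred on the point set under
assessment — and everything else in the package goes through it.  An
equal-area projection is the right choice because the quantity the IUCN
thresholds test is *area*; local azimuthal centring keeps distance distortion
negligible at the extents of a single taxon's range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import transform as shapely_transform

#: Authalic earth radius in km (sphere with the same surface area as the
#: WGS84 ellipsoid).  Used consistently for distances, projection and areas,
#: and echoed into run metadata.
EARTH_RADIUS_KM = 6371.0072

#: Longitude span (degrees) beyond which the local planar frame is flagged
#: as unreliable for very wide-ranging taxa.
WIDE_RANGE_LON_SPAN_DEG = 120.0


class MeridianSpanError(ValueError):
    """Raised when a point set appears to span the 180th meridian.

    Ranges crossing the antimeridian cannot be handled by a single local
    planar frame; affected taxa are refused with a warning rather than
    assessed incorrectly.
    """


def great_circle_distance_km(p, q) -> float:
    """Great-circle distance between two (lat, lon) points in km.

    Haversine on the authalic sphere: symmetric, non-negative and zero iff
    the points coincide.
    """
    lat1, lon1 = math.radians(p[0]), math.radians(p[1])
    lat2, lon2 = math.radians(q[0]), math.radians(q[1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def pairwise_distances_km(latlon: np.ndarray) -> np.ndarray:
    """Full symmetric matrix of great-circle distances (km) for an (n, 2)
    array of (lat, lon) rows.  Vectorised haversine."""
    pts = np.radians(np.asarray(latlon, dtype=float))
    lat = pts[:, 0][:, None]
    lon = pts[:, 1][:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def max_pairwise_distance_km(latlon: np.ndarray) -> float:
    """Maximum interoccurrence great-circle distance in km (0 for n < 2)."""
    latlon = np.asarray(latlon, dtype=float)
    if latlon.shape[0] < 2:
        return 0.0
    return float(pairwise_distances_km(latlon).max())


@dataclass(frozen=True)
class LocalProjection:
    """Lambert azimuthal equal-area projection centred at (lat0, lon0).

    Forward maps WGS84 degrees to planar km; inverse maps back.  Equal-area
    by construction on the authalic sphere, so planar polygon areas equal
    geodesic areas exactly (up to float error).
    """

    lat0: float
    lon0: float

    @classmethod
    def for_points(cls, latlon: np.ndarray) -> "LocalProjection":
        """Projection centred on the coordinate-wise mean of a point set.

        Raises :class:`MeridianSpanError` if the longitudes span more than
        180 degrees, which indicates an antimeridian-crossing range.
        """
        latlon = np.atleast_2d(np.asarray(latlon, dtype=float))
        lon_span = float(latlon[:, 1].max() - latlon[:, 1].min())
        if lon_span > 180.0:
            raise MeridianSpanError(
                "occurrences span more than 180 degrees of longitude; the "
                "range appears to cross the 180th meridian and cannot be "
                "assessed in a single local planar frame"
            )
        return cls(float(latlon[:, 0].mean()), float(latlon[:, 1].mean()))

    def forward(self, latlon: np.ndarray) -> np.ndarray:
        """Project (n, 2) array of (lat, lon) degrees to (n, 2) planar km."""
        latlon = np.atleast_2d(np.asarray(latlon, dtype=float))
        phi = np.radians(latlon[:, 0])
        lam = np.radians(latlon[:, 1])
        phi0 = math.radians(self.lat0)
        lam0 = math.radians(self.lon0)
        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
        if np.any(cos_c <= -1.0 + 1e-12):
            raise ValueError("point antipodal to projection center")
        k = np.sqrt(2.0 / (1.0 + cos_c))
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
        y = EARTH_RADIUS_KM * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
        )
        return np.column_stack([x, y])

    def inverse(self, xy: np.ndarray) -> np.ndarray:
        """Map (n, 2) planar km back to (n, 2) (lat, lon) degrees."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x = xy[:, 0]
        y = xy[:, 1]
        rho = np.hypot(x, y)
        phi0 = math.radians(self.lat0)
        lam0 = math.radians(self.lon0)
        with np.errstate(invalid="ignore"):
            c = 2.0 * np.arcsin(np.minimum(1.0, rho / (2.0 * EARTH_RADIUS_KM)))
        sin_c, cos_c = np.sin(c), np.cos(c)
        # Guard rho == 0: the centre maps to itself.
        safe_rho = np.where(rho == 0.0, 1.0, rho)
        phi = np.arcsin(cos_c * math.sin(phi0) + y * sin_c * math.cos(phi0) / safe_rho)
        lam = lam0 + np.arctan2(
            x * sin_c, safe_rho * math.cos(phi0) * cos_c - y * math.sin(phi0) * sin_c
        )
        lat = np.degrees(np.where(rho == 0.0, phi0, phi))
        lon = np.degrees(np.where(rho == 0.0, lam0, lam))
        return np.column_stack([lat, lon])

    # shapely.ops.transform adapters ------------------------------------
    def _fwd_xy(self, lon, lat):
        out = self.forward(np.column_stack([np.atleast_1d(lat), np.atleast_1d(lon)]))
        return out[:, 0], out[:, 1]

    def _inv_xy(self, x, y):
        out = self.inverse(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
        return out[:, 1], out[:, 0]

    def forward_geom(self, geom):
        """Project a shapely geometry in (lon, lat) degrees to planar km."""
        return shapely_transform(self._fwd_xy, geom)

    def inverse_geom(self, geom):
        """Map a planar-km shapely geometry back to (lon, lat) degrees."""
        return shapely_transform(self._inv_xy, geom)


def project(latlon: np.ndarray, proj: LocalProjection) -> np.ndarray:
    """Functional alias for :meth:`LocalProjection.forward`."""
    return proj.forward(latlon)


def polygon_area_km2(geom, proj: LocalProjection | None = None) -> float:
    """Geodesic area in km² of a WGS84 polygon or multipolygon.

    The geometry (shapely, (lon, lat) axis order) is projected to a local
    equal-area frame centred on its centroid (or an explicit projection) and
    the planar area is returned.  Degenerate geometry yields 0 with a warning.
    Additive over disjoint parts.
    """
    if geom is None or geom.is_empty:
        warnings.warn("degenerate geometry: area reported as 0", stacklevel=2)
        return 0.0
    if not isinstance(geom, (Polygon, MultiPolygon)):
        warnings.warn(
            f"non-areal geometry {geom.geom_type}: area reported as 0", stacklevel=2
        )
        return 0.0
    if proj is None:
        c = geom.centroid
        proj = LocalProjection(c.y, c.x)
    return float(proj.forward_geom(geom).area)
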