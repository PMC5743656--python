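"""Extent of occurrence (EOO): hull construction and degenerate cases.

EOO is the area within the shortest continuous boundary encompassing all
known occurrences — operationally a convex hull, or (where the range is
strongly concave or disjunct) an alpha hull built from the Delaunay
triangulation.  Degenerate point sets get the conventional handling:

* fewer than three unique occurrences -> EOO undefined (``NA``), warning;
* all points on a straight segment -> the hull would have zero area, so the
  segment is dilated by a fixed buffer (default 0.1 degrees) and that area
  is reported, with a warning;
* optional cropping polygons (e.g. sea masks) are subtracted from the hull
  before area computation — always with a warning, since cropping EOO is
  explicitly discouraged by the IUCN guidelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import LineString, MultiPoint, MultiPolygon, Point, Polygon
from shapely.ops import unary_union

from .geodesy import LocalProjection, polygon_area_km2

CROPPING_WARNING = (
    "EOO cropped by exclusion polygons; note that excluding areas from EOO "
    "is explicitly discouraged by the IUCN guidelines"
)

#: Smallest singular value (km) of the centered planar coordinate matrix
#: below which a point set is treated as a straight segment.
COLLINEARITY_TOL_KM = 1e-6


@dataclass
class EooResult:
    """EOO of one taxon: area, hull polygon (WGS84), method and warnings."""

    area_km2: float | None
    hull: Polygon | MultiPolygon | None
    method_used: str  # convex_hull | alpha_hull | segment_buffer | undefined
    warnings: list[str] = field(default_factory=list)


def _is_collinear(xy: np.ndarray, latlon: np.ndarray) -> bool:
    """Straight-segment test.

    Primary criterion: smallest singular value of the centred planar (km)
    coordinates below ``COLLINEARITY_TOL_KM``.  Points exactly collinear in
    degree space also qualify — the equal-area projection bends off-centre
    lines by more than the km tolerance, but such inputs are the degenerate
    case the buffer rule exists for.
    """
    centered = xy - xy.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[-1] < COLLINEARITY_TOL_KM:
        return True
    d = latlon - latlon[0]
    cross = d[:, 0] * d[1, 1] - d[:, 1] * d[1, 0] if latlon.shape[0] > 1 else np.zeros(1)
    return bool(np.allclose(cross, 0.0, atol=1e-12))


def convex_hull(xy: np.ndarray) -> Polygon:
    """Convex hull of planar points; raises on collinear input.

    The caller is expected to route collinear sets to the segment-buffer
    path instead.
    """
    hull = MultiPoint([tuple(p) for p in np.asarray(xy, dtype=float)]).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("convex hull of collinear points is degenerate")
    return hull


def _circumradii(xy: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumscribed-circle radius of each Delaunay triangle (vectorised)."""
    a = xy[simplices[:, 0]]
    b = xy[simplices[:, 1]]
    c = xy[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0.0] = np.inf
    return r


def alpha_hull(xy: np.ndarray, alpha_km: float) -> Polygon | MultiPolygon | None:
    """Union of Delaunay triangles with circumradius <= ``alpha_km``.

    Converges to the convex hull as alpha grows; may be multi-part for
    disjunct ranges.  Returns None when no triangle qualifies.
    """
    if alpha_km <= 0:
        raise ValueError("alpha must be positive")
    xy = np.asarray(xy, dtype=float)
    try:
        tri = Delaunay(xy)
    except QhullError as e:
        raise ValueError("Delaunay triangulation failed (degenerate input)") from e
    keep = tri.simplices[_circumradii(xy, tri.simplices) <= alpha_km]
    if keep.shape[0] == 0:
        return None
    triangles = [Polygon(xy[s]) for s in keep]
    merged = unary_union(triangles)
    if merged.is_empty or merged.geom_type not in ("Polygon", "MultiPolygon"):
        return None
    return merged


def _segment_buffer_hull(latlon: np.ndarray, buffer_deg: float) -> Polygon:
    """Degree-space dilation of the straight segment through the points."""
    pts = np.asarray(latlon, dtype=float)
    if pts.shape[0] == 1 or np.allclose(pts, pts[0]):
        geom = Point(pts[0, 1], pts[0, 0])
    else:
        # order along the dominant axis so the LineString is the full segment
        spread = pts.max(axis=0) - pts.min(axis=0)
        order = np.argsort(pts[:, int(np.argmax(spread))])
        geom = LineString([(lon, lat) for lat, lon in pts[order]])
    return geom.buffer(buffer_deg, quad_segs=64)


def compute_eoo(
    points: np.ndarray,
    method: str = "convex_hull",
    alpha_km: float = 50.0,
    segment_buffer_deg: float = 0.1,
    exclude_area=None,
    proj: LocalProjection | None = None,
) -> EooResult:
    """EOO of one taxon's deduplicated (lat, lon) points.

    Parameters
    ----------
    points
        (n, 2) array of unique (lat, lon) pairs.
    method
        ``"convex_hull"`` (default) or ``"alpha_hull"``.
    alpha_km
        Circumradius threshold of the alpha hull, km.
    segment_buffer_deg
        Dilation (degrees) applied to exactly-collinear point sets.
    exclude_area
        Optional iterable of WGS84 polygons subtracted from the hull before
        the area is computed (discouraged by IUCN; always warned).
    proj
        Local equal-area frame; derived from the points when omitted.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("empty point set")
    points = np.unique(points, axis=0)  # defensive dedup; order-irrelevant here
    if method not in ("convex_hull", "alpha_hull"):
        raise ValueError(f"unknown EOO method {method!r}")
    if alpha_km <= 0:
        raise ValueError("alpha must be positive")

    warns: list[str] = []
    if points.shape[0] < 3:
        warns.append("EOO not computed: fewer than three unique occurrences")
        return EooResult(None, None, "undefined", warns)

    if proj is None:
        proj = LocalProjection.for_points(points)
    xy = proj.forward(points)

    if _is_collinear(xy, points):
        warns.append(
            "occurrences form a straight segment (EOO would be zero); segment "
            f"buffered by {segment_buffer_deg} degrees"
        )
        hull = _segment_buffer_hull(points, segment_buffer_deg)
        method_used = "segment_buffer"
    elif method == "convex_hull":
        hull = proj.inverse_geom(convex_hull(xy))
        method_used = "convex_hull"
    else:
        planar = alpha_hull(xy, alpha_km)
        if planar is None:
            warns.append(
                f"alpha hull undefined: no Delaunay triangle has circumradius "
                f"<= {alpha_km} km"
            )
            return EooResult(None, None, "undefined", warns)
        if planar.geom_type == "MultiPolygon":
            warns.append(
                "alpha hull has multiple disjoint parts; reported EOO is the "
                "summed area, which deviates from the strict single-boundary "
                "definition"
            )
        hull = proj.inverse_geom(planar)
        method_used = "alpha_hull"

    if exclude_area is not None:
        excl = list(exclude_area) if not hasattr(exclude_area, "geoms") else [exclude_area]
        if excl:
            warns.append(CROPPING_WARNING)
            cropped = hull
            for g in excl:
                g = g[1] if isinstance(g, tuple) else g
                cropped = cropped.difference(g)
            hull = cropped
            if hull.is_empty:
                warns.append("EOO entirely within excluded area; area is 0")
                return EooResult(0.0, hull, method_used, warns)

    return EooResult(polygon_area_km2(hull, proj=proj), hull, method_used, warns)
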