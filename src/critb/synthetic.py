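"""Deterministic synthetic occurrence and protected-area generators.

Real multi-taxon assessments run on herbarium/museum compilations or GBIF
downloads; this module builds structurally similar inputs — several taxa,
each a set of clustered points scattered over a region, optionally overlain
by a mosaic of rectangular protected areas — with known generating
parameters, so every stage of the pipeline is testable offline.  All
randomness flows through one seeded ``numpy`` generator; the same seed gives
the same table on any platform.

``preset_scenarios`` covers the named degenerate regimes: fewer than three
unique points, exactly collinear points, all points inside a single
protected area, a protected-area boundary splitting a pair of points closer
than one grid cell, and a widespread sparsely collected range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geodesy import LocalProjection
from .occ_io import ProtectedAreaSet


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic multi-taxon scene.

    Distances are km in the local planar frame centred on ``region_center``;
    ``region_extent_km`` is the side of the square region cluster centres
    are drawn in.  ``layout`` selects hand-built degenerate layouts
    (``"collinear"``, ``"single"``) instead of the clustered default.
    """

    seed: int = 0
    n_taxa: int = 5
    clusters_per_taxon: int = 3
    points_per_cluster: int = 10
    cluster_sd_km: float = 2.0
    cluster_spread_km: float = 100.0
    region_center: tuple[float, float] = (0.0, 25.0)  # (lat, lon)
    region_extent_km: float = 600.0
    pa_fraction: float = 0.0
    year_range: tuple[int, int] | None = (1950, 2020)
    layout: str = "clustered"

    def __post_init__(self):
        if min(self.n_taxa, self.clusters_per_taxon, self.points_per_cluster) < 1:
            raise ValueError("counts must be >= 1")
        if self.cluster_sd_km <= 0 or self.cluster_spread_km <= 0:
            raise ValueError("cluster sd and spread must be positive")
        if not (0.0 <= self.pa_fraction < 1.0):
            raise ValueError("pa_fraction must be in [0, 1)")
        if self.layout == "clustered" and self.region_extent_km < self.cluster_spread_km:
            raise ValueError("region extent too small for the requested cluster spread")


def _projection(spec: ScenarioSpec) -> LocalProjection:
    return LocalProjection(*spec.region_center)


def generate_occurrences(spec: ScenarioSpec) -> tuple[pd.DataFrame, dict]:
    """Occurrence table (ddlat/ddlon/tax[/year] columns) plus ground truth.

    Ground truth records, per taxon, the planar cluster centres and the
    generating parameters, so tests can compare recovered range metrics
    against the construction.
    """
    rng = np.random.default_rng(spec.seed)
    proj = _projection(spec)
    half = spec.region_extent_km / 2.0
    rows: list[dict] = []
    truth: dict = {"spec": spec, "taxa": {}}

    for t in range(spec.n_taxa):
        taxon = f"Taxon_{t:03d}"
        if spec.layout == "single":
            xy = rng.uniform(-half, half, size=(1, 2))
        elif spec.layout == "collinear":
            # three points on the central meridian (x = 0), exactly collinear
            ys = np.sort(rng.uniform(-half, half, size=3))
            xy = np.column_stack([np.zeros(3), ys])
        else:
            # cluster centres spread over the region, points scattered around
            centers = rng.uniform(-half, half, size=(spec.clusters_per_taxon, 2))
            # rescale so the centre spread matches cluster_spread_km
            if spec.clusters_per_taxon > 1:
                span = np.abs(centers - centers.mean(axis=0)).max()
                if span > 0:
                    centers *= (spec.cluster_spread_km / 2.0) / span
            pts = [
                c + rng.normal(0.0, spec.cluster_sd_km, size=(spec.points_per_cluster, 2))
                for c in centers
            ]
            xy = np.vstack(pts)
        latlon = proj.inverse(xy)
        years = None
        if spec.year_range is not None:
            years = rng.integers(spec.year_range[0], spec.year_range[1] + 1, size=len(latlon))
        for k, (lat, lon) in enumerate(latlon):
            row = {"ddlat": round(float(lat), 6), "ddlon": round(float(lon), 6), "tax": taxon}
            if years is not None:
                row["year"] = int(years[k])
            rows.append(row)
        truth["taxa"][taxon] = {
            "planar_points": xy,
            "n_points": len(xy),
            "layout": spec.layout,
        }
    return pd.DataFrame(rows), truth


def generate_protected_areas(spec: ScenarioSpec) -> ProtectedAreaSet:
    """Mosaic of disjoint axis-aligned rectangular PAs covering about
    ``pa_fraction`` of the region, deterministic per seed.

    Rectangles are chosen as cells of a coarse partition of the region, so
    disjointness holds by construction.
    """
    if spec.pa_fraction == 0.0:
        return ProtectedAreaSet([])
    rng = np.random.default_rng(spec.seed + 1)
    proj = _projection(spec)
    half = spec.region_extent_km / 2.0
    n_div = 6  # 36 candidate cells
    n_pick = int(round(spec.pa_fraction * n_div * n_div))
    if n_pick < 1:
        raise ValueError("pa_fraction too small for the rectangle partition")
    cells = [(i, j) for i in range(n_div) for j in range(n_div)]
    chosen = rng.choice(len(cells), size=n_pick, replace=False)
    side = spec.region_extent_km / n_div
    areas = []
    for k, ci in enumerate(sorted(chosen)):
        i, j = cells[ci]
        x0, y0 = -half + i * side, -half + j * side
        # shrink slightly so neighbouring picks stay strictly disjoint
        rect = box(x0 + 0.01 * side, y0 + 0.01 * side,
                   x0 + 0.99 * side, y0 + 0.99 * side)
        areas.append((f"PA_{k:02d}", proj.inverse_geom(rect)))
    return ProtectedAreaSet(areas)


def preset_scenarios() -> dict[str, ScenarioSpec]:
    """Named scenarios exercising each degenerate branch of the pipeline."""
    return {
        # one tight cluster, everything within a few km -> CR regime
        "narrow_endemic": ScenarioSpec(
            seed=11, n_taxa=1, clusters_per_taxon=1, points_per_cluster=30,
            cluster_sd_km=1.0, cluster_spread_km=5.0, region_extent_km=50.0,
        ),
        # many dispersed clusters over >1,000 km -> NT/LC regime
        "widespread": ScenarioSpec(
            seed=12, n_taxa=1, clusters_per_taxon=12, points_per_cluster=4,
            cluster_sd_km=20.0, cluster_spread_km=1500.0, region_extent_km=1600.0,
        ),
        # PA mosaic over a moderately spread taxon (PA-method contrasts)
        "pa_split": ScenarioSpec(
            seed=13, n_taxa=1, clusters_per_taxon=4, points_per_cluster=8,
            cluster_sd_km=5.0, cluster_spread_km=200.0, region_extent_km=400.0,
            pa_fraction=0.3,
        ),
        # three points on one meridian -> segment-buffer EOO path
        "collinear": ScenarioSpec(
            seed=14, n_taxa=1, layout="collinear", region_extent_km=100.0,
        ),
        # one occurrence -> EOO undefined path, CR B2a pattern
        "single_record": ScenarioSpec(
            seed=15, n_taxa=1, layout="single", region_extent_km=50.0,
        ),
    }
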