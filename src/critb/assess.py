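"""Batch orchestration: per-taxon assessment, result tables, maps, grids.

``assess_taxon`` chains the range metrics (EOO -> AOO -> locations ->
subpopulations), applies the EOO >= AOO correction (an EOO smaller than the
AOO is replaced by the AOO before ranking), and runs the criterion-B rule
engine.  ``assess_batch`` does this for every taxon in a dataset, never
aborting on a single taxon — per-taxon failures become warnings and a
not-assessable row — and writes a CSV plus a JSON metadata sidecar echoing
the full configuration, earth model and thresholds.  Warnings are data:
each row carries its own list, because console logs are useless for
auditing a thousand-taxon run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from . import __version__
from .aoo_locations import compute_aoo, count_locations, sliding_cell_size_km
from .categorize import CategoryResult, SeverityRank, ThresholdTable, categorize
from .eoo import EooResult, compute_eoo
from .geodesy import (
    EARTH_RADIUS_KM,
    WIDE_RANGE_LON_SPAN_DEG,
    LocalProjection,
    MeridianSpanError,
)
from .occ_io import ProtectedAreaSet, TaxonOccurrences
from .subpop import count_subpopulations

CSV_COLUMNS = [
    "taxon", "n_records", "n_unique_occurrences", "eoo_km2", "aoo_km2",
    "n_subpopulations", "n_locations", "n_occurrences_in_pa",
    "proportion_in_pa", "category_B1", "category_B2", "final_category",
    "criterion_code", "warnings",
]


@dataclass(frozen=True)
class AssessmentConfig:
    """Every user-tunable parameter of the assessment method.

    Cell sizes are grid-cell *side lengths* in km.  ``loc_cell_fraction``
    switches the locations grid to the sliding scale (side = fraction of
    the maximum interoccurrence distance); when None the fixed
    ``loc_cell_km`` is used.
    """

    eoo_method: str = "convex_hull"  # convex_hull | alpha_hull
    alpha_km: float = 50.0
    segment_buffer_deg: float = 0.1
    aoo_cell_km: float = 2.0
    loc_cell_km: float = 10.0
    loc_cell_fraction: float | None = None
    origin_shifts: int = 4
    subpop_radius_km: float = 5.0
    pa_method: str = "none"  # none | no_more_than_one | other
    thresholds: ThresholdTable = field(default_factory=ThresholdTable)
    draw_maps: bool = False
    grid_summary_deg: float | None = None

    def to_metadata(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        d["earth_model"] = f"authalic sphere, R = {EARTH_RADIUS_KM} km"
        d["projection"] = "Lambert azimuthal equal-area, centred per taxon"
        return d


@dataclass
class TaxonAssessment:
    """One result row: range metrics, categories and per-taxon warnings."""

    taxon: str
    n_records: int = 0
    n_unique_occurrences: int = 0
    assessable: bool = False
    eoo_km2: float | None = None
    eoo_result: EooResult | None = None
    aoo_km2: float | None = None
    n_subpopulations: int | None = None
    n_locations: int | None = None
    n_occurrences_in_pa: int = 0
    proportion_in_pa: float | None = None
    category: CategoryResult | None = None
    warnings: list[str] = field(default_factory=list)
    # geometry layers kept for map rendering / GeoJSON export
    subpop_buffers: list = field(default_factory=list)
    location_cells: list = field(default_factory=list)

    @property
    def final_category_label(self) -> str:
        if not self.assessable or self.category is None:
            return "NA"
        return self.category.final_category.label


def assess_taxon(
    occ: TaxonOccurrences,
    config: AssessmentConfig = AssessmentConfig(),
    pas: ProtectedAreaSet | None = None,
    exclude_area=None,
) -> TaxonAssessment:
    """Assess one taxon; degenerate inputs produce warnings, not failures."""
    result = TaxonAssessment(taxon=occ.taxon, n_records=occ.n_records)
    if occ.n_records == 0:
        result.warnings.append("no valid georeferenced records; taxon not assessable")
        return result
    points = occ.unique_points
    result.n_unique_occurrences = points.shape[0]

    try:
        proj = LocalProjection.for_points(points)
    except MeridianSpanError as e:
        result.warnings.append(str(e))
        return result
    lon_span = float(points[:, 1].max() - points[:, 1].min())
    if lon_span > WIDE_RANGE_LON_SPAN_DEG:
        result.warnings.append(
            f"longitudinal span {lon_span:.1f} degrees exceeds "
            f"{WIDE_RANGE_LON_SPAN_DEG:g}; projection unreliable, estimates "
            "may be biased for this wide-ranging taxon"
        )

    # EOO
    eoo_res = compute_eoo(
        points, method=config.eoo_method, alpha_km=config.alpha_km,
        segment_buffer_deg=config.segment_buffer_deg,
        exclude_area=exclude_area, proj=proj,
    )
    result.eoo_result = eoo_res
    result.warnings.extend(eoo_res.warnings)

    # AOO
    aoo_res = compute_aoo(points, config.aoo_cell_km, config.origin_shifts, proj=proj)
    result.aoo_km2 = aoo_res.area_km2

    # EOO >= AOO correction, applied before any ranking
    eoo_km2 = eoo_res.area_km2
    if eoo_km2 is not None and eoo_km2 < aoo_res.area_km2:
        result.warnings.append(
            f"EOO ({eoo_km2:.3f} km2) smaller than AOO "
            f"({aoo_res.area_km2:.3f} km2); EOO set equal to AOO"
        )
        eoo_km2 = aoo_res.area_km2
    result.eoo_km2 = eoo_km2

    # locations
    if config.loc_cell_fraction is not None:
        loc_cell, w = sliding_cell_size_km(
            points, config.loc_cell_fraction, fallback_km=config.loc_cell_km
        )
        result.warnings.extend(w)
    else:
        loc_cell = config.loc_cell_km
    loc_res = count_locations(
        points, cell_side_km=loc_cell, origin_shifts=config.origin_shifts,
        pa_method=config.pa_method, pas=pas, proj=proj,
    )
    result.n_locations = loc_res.n_locations
    result.location_cells = loc_res.cell_footprints
    result.warnings.extend(loc_res.warnings)
    if pas is not None and len(pas) > 0:
        in_pa = sum(
            1 for r in occ.records if pas.containing_area(r.latitude, r.longitude) is not None
        )
        result.n_occurrences_in_pa = in_pa
        result.proportion_in_pa = in_pa / occ.n_records

    # subpopulations
    sub_res = count_subpopulations(
        points, config.subpop_radius_km, proj=proj, build_buffers=config.draw_maps
    )
    result.n_subpopulations = sub_res.n_subpopulations
    result.subpop_buffers = sub_res.buffers

    result.category = categorize(
        result.eoo_km2, result.aoo_km2, result.n_locations, config.thresholds
    )
    result.assessable = True
    return result


def _row(a: TaxonAssessment) -> dict:
    cat = a.category
    return {
        "taxon": a.taxon,
        "n_records": a.n_records,
        "n_unique_occurrences": a.n_unique_occurrences,
        "eoo_km2": round(a.eoo_km2, 3) if a.eoo_km2 is not None else None,
        "aoo_km2": round(a.aoo_km2, 3) if a.aoo_km2 is not None else None,
        "n_subpopulations": a.n_subpopulations,
        "n_locations": a.n_locations,
        "n_occurrences_in_pa": a.n_occurrences_in_pa,
        "proportion_in_pa": round(a.proportion_in_pa, 4) if a.proportion_in_pa is not None else None,
        "category_B1": (
            None if cat is None or cat.category_B1 is None else cat.category_B1.label
        ),
        "category_B2": None if cat is None else cat.category_B2.label,
        "final_category": a.final_category_label,
        "criterion_code": None if cat is None else cat.criterion_code,
        "warnings": "; ".join(a.warnings),
    }


def assess_batch(
    dataset: list[TaxonOccurrences],
    config: AssessmentConfig = AssessmentConfig(),
    pas: ProtectedAreaSet | None = None,
    exclude_area=None,
    out_dir: str | Path | None = None,
) -> tuple[list[TaxonAssessment], pd.DataFrame]:
    """Assess every taxon; optionally write results.csv + metadata + maps.

    One row per input taxon (not-assessable ones included) in input order;
    the output is deterministic for identical inputs and configuration.
    """
    if not dataset:
        raise ValueError("empty dataset: no taxa to assess")
    assessments = []
    for occ in dataset:
        try:
            assessments.append(assess_taxon(occ, config, pas, exclude_area))
        except Exception as e:  # per-taxon failure must not abort the batch
            failed = TaxonAssessment(taxon=occ.taxon, n_records=occ.n_records)
            failed.warnings.append(f"assessment failed: {e}")
            assessments.append(failed)

    table = pd.DataFrame([_row(a) for a in assessments], columns=CSV_COLUMNS)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "results.csv", index=False)
        (out_dir / "run_metadata.json").write_text(
            json.dumps({"critb_version": __version__, "config": config.to_metadata(),
                        "n_taxa": len(dataset)}, indent=2)
        )
        _write_geojson_sidecars(assessments, out_dir)
        if config.draw_maps:
            maps_dir = out_dir / "maps"
            maps_dir.mkdir(exist_ok=True)
            for occ, a in zip(dataset, assessments):
                try:
                    render_taxon_map(a, occ, pas, maps_dir / f"{_safe(a.taxon)}.png")
                except Exception as e:
                    a.warnings.append(f"map rendering failed: {e}")
    return assessments, table


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)


def _write_geojson_sidecars(assessments: list[TaxonAssessment], out_dir: Path) -> None:
    features = []
    for a in assessments:
        if a.eoo_result is not None and a.eoo_result.hull is not None:
            features.append({
                "type": "Feature",
                "geometry": mapping(a.eoo_result.hull),
                "properties": {"taxon": a.taxon, "layer": "eoo_hull",
                               "method": a.eoo_result.method_used},
            })
        for poly in a.location_cells:
            features.append({
                "type": "Feature", "geometry": mapping(poly),
                "properties": {"taxon": a.taxon, "layer": "location_cell"},
            })
        for poly in a.subpop_buffers:
            features.append({
                "type": "Feature", "geometry": mapping(poly),
                "properties": {"taxon": a.taxon, "layer": "subpopulation"},
            })
    (out_dir / "geometries.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def render_taxon_map(
    assessment: TaxonAssessment,
    occ: TaxonOccurrences,
    pas: ProtectedAreaSet | None,
    path: str | Path,
) -> Path:
    """Per-taxon PNG: occurrences (coloured by PA membership), EOO hull,
    location cells, subpopulation buffers, a parameter inset, and a
    collections-per-year bar plot when year data exist.  Works headless."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    years = occ.years
    fig = plt.figure(figsize=(8, 7 if years else 6))
    ax = fig.add_axes([0.08, 0.32 if years else 0.12, 0.88, 0.62 if years else 0.82])

    def draw_poly(geom, **kw):
        geoms = geom.geoms if hasattr(geom, "geoms") else [geom]
        for g in geoms:
            if g.geom_type == "Polygon":
                xs, ys = g.exterior.xy
                ax.fill(xs, ys, **kw)

    if pas is not None:
        for _, poly in pas:
            draw_poly(poly, color="tab:green", alpha=0.15, zorder=1)
    if assessment.eoo_result is not None and assessment.eoo_result.hull is not None:
        draw_poly(assessment.eoo_result.hull, color="grey", alpha=0.3, zorder=2)
    for cell in assessment.location_cells:
        draw_poly(cell, color="pink", alpha=0.5, zorder=3)
    for buf in assessment.subpop_buffers:
        draw_poly(buf, facecolor="none", edgecolor="tab:blue", alpha=0.0, zorder=4)
        geoms = buf.geoms if hasattr(buf, "geoms") else [buf]
        for g in geoms:
            xs, ys = g.exterior.xy
            ax.plot(xs, ys, color="tab:blue", lw=0.8, zorder=4)
    lats = [r.latitude for r in occ.records]
    lons = [r.longitude for r in occ.records]
    in_pa = [
        pas is not None and pas.containing_area(la, lo) is not None
        for la, lo in zip(lats, lons)
    ]
    ax.scatter([lo for lo, m in zip(lons, in_pa) if not m],
               [la for la, m in zip(lats, in_pa) if not m],
               c="black", s=12, zorder=5, label="outside PA")
    if any(in_pa):
        ax.scatter([lo for lo, m in zip(lons, in_pa) if m],
                   [la for la, m in zip(lats, in_pa) if m],
                   c="tab:blue", s=12, zorder=5, label="inside PA")
        ax.legend(loc="upper right", fontsize=7)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(assessment.taxon, fontsize=10, style="italic")

    eoo_txt = "NA" if assessment.eoo_km2 is None else f"{assessment.eoo_km2:,.1f}"
    inset = (
        f"EOO: {eoo_txt} km$^2$   AOO: {assessment.aoo_km2:,.1f} km$^2$\n"
        f"locations: {assessment.n_locations}   "
        f"subpopulations: {assessment.n_subpopulations}\n"
        f"preliminary status: {assessment.final_category_label} "
        f"{assessment.category.criterion_code if assessment.category else ''}"
    )
    fig.text(0.08, 0.02, inset, fontsize=8,
             bbox=dict(facecolor="0.9", edgecolor="0.6"))

    if years:
        axh = fig.add_axes([0.55, 0.04, 0.41, 0.18])
        lo, hi = min(years), max(years)
        axh.hist(years, bins=range(lo, hi + 2), color="0.4")
        axh.set_xlabel("collection year", fontsize=7)
        axh.tick_params(labelsize=6)

    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


@dataclass
class GridSummaryCell:
    """Per-cell record/taxon/threat counts for multi-species summary maps."""

    cell: tuple[int, int]  # (lat index, lon index), origin at (-90, -180)
    lat_min: float
    lon_min: float
    n_records: int = 0
    n_taxa: int = 0
    n_threatened_taxa: int = 0

    @property
    def proportion_threatened(self) -> float | None:
        return self.n_threatened_taxa / self.n_taxa if self.n_taxa else None


def grid_summary(
    assessments: list[TaxonAssessment],
    dataset: list[TaxonOccurrences],
    cell_size_deg: float = 0.5,
    map_path: str | Path | None = None,
) -> list[GridSummaryCell]:
    """Lat/lon grid summary of a batch: records, taxa and threatened taxa
    per cell.  A taxon is threatened iff its final category is CR, EN or VU;
    every record lands in exactly one cell (floor convention, origin at
    (-90, -180))."""
    if cell_size_deg <= 0:
        raise ValueError("cell size must be positive")
    threat = {
        a.taxon: (a.category is not None and a.category.final_category.is_threatened)
        for a in assessments
    }
    cells: dict[tuple[int, int], GridSummaryCell] = {}
    taxa_per_cell: dict[tuple[int, int], set[str]] = {}
    for occ in dataset:
        for r in occ.records:
            key = (
                int(np.floor((r.latitude + 90.0) / cell_size_deg)),
                int(np.floor((r.longitude + 180.0) / cell_size_deg)),
            )
            cell = cells.setdefault(
                key,
                GridSummaryCell(
                    key,
                    lat_min=-90.0 + key[0] * cell_size_deg,
                    lon_min=-180.0 + key[1] * cell_size_deg,
                ),
            )
            cell.n_records += 1
            taxa_per_cell.setdefault(key, set()).add(occ.taxon)
    for key, taxa in taxa_per_cell.items():
        cells[key].n_taxa = len(taxa)
        cells[key].n_threatened_taxa = sum(1 for t in taxa if threat.get(t, False))

    out = [cells[k] for k in sorted(cells)]
    if map_path is not None:
        _render_grid_map(out, cell_size_deg, Path(map_path))
    return out


def _render_grid_map(cells: list[GridSummaryCell], cell_size_deg: float, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(8, 6))
    vals = [c.proportion_threatened or 0.0 for c in cells]
    vmax = max(vals) if vals else 1.0
    cmap = plt.get_cmap("Reds")
    for c, v in zip(cells, vals):
        ax.add_patch(Rectangle(
            (c.lon_min, c.lat_min), cell_size_deg, cell_size_deg,
            facecolor=cmap(v / vmax if vmax else 0.0), edgecolor="0.7", lw=0.3,
        ))
    ax.autoscale_view()
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(f"proportion of threatened taxa per {cell_size_deg}-degree cell")
    fig.savefig(path, dpi=100)
    plt.close(fig)
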