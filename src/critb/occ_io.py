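"""Reading, validating and organising occurrence tables and polygon layers.

Input contract: a delimited text file (comma, semicolon or tab) with one row
per collection, mandatory decimal-degree WGS84 latitude/longitude and a taxon
name (default column names ``ddlat`` / ``ddlon`` / ``tax``), optional
collection year and higher taxon.  Rows with unparseable or out-of-range
coordinates are dropped with a warning naming the row; a taxon whose every
row is invalid is kept with zero records and flagged not-assessable
downstream.  Polygon layers (protected areas, cropping masks) are GeoJSON
feature collections in WGS84.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, shape
from shapely.validation import make_valid

DEFAULT_COLUMNS = {"latitude": "ddlat", "longitude": "ddlon", "taxon": "tax",
                   "year": "year", "higher_taxon": "higher_tax"}


@dataclass(frozen=True)
class OccurrenceRecord:
    """One validated georeferenced collection of a taxon."""

    taxon: str
    latitude: float
    longitude: float
    year: int | None = None
    higher_taxon: str | None = None


@dataclass
class TaxonOccurrences:
    """All accepted records of one taxon plus the deduplicated point set.

    ``unique_points`` holds distinct (lat, lon) pairs compared at full float
    precision, in first-appearance order.  A taxon with zero records is a
    valid, not-assessable entry (it still gets a result row).
    """

    taxon: str
    records: list[OccurrenceRecord] = field(default_factory=list)

    @property
    def unique_points(self) -> np.ndarray:
        seen: dict[tuple[float, float], None] = {}
        for r in self.records:
            seen.setdefault((r.latitude, r.longitude), None)
        if not seen:
            return np.empty((0, 2), dtype=float)
        return np.array(list(seen.keys()), dtype=float)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_unique(self) -> int:
        return self.unique_points.shape[0]

    @property
    def years(self) -> list[int]:
        return [r.year for r in self.records if r.year is not None]


@dataclass
class ProtectedAreaSet:
    """Collection of (id, polygon) protected areas in WGS84.

    Polygons use shapely's (lon, lat) axis order.  Invalid rings are repaired
    with ``make_valid`` at load time, so downstream point-in-polygon tests
    are well defined.
    """

    areas: list[tuple[str, Polygon | MultiPolygon]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.areas)

    def __iter__(self):
        return iter(self.areas)

    def containing_area(self, lat: float, lon: float) -> str | None:
        """Id of the first protected area covering the point, else None.

        Boundary points count as inside (``covers``), the conservative
        convention: fewer, not more, locations.
        """
        from shapely.geometry import Point

        p = Point(lon, lat)
        for pa_id, poly in self.areas:
            if poly.covers(p):
                return pa_id
        return None


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text(encoding="utf-8", errors="replace")[:4096].splitlines()
    first = head[0] if head else ""
    counts = {d: first.count(d) for d in (",", ";", "\t")}
    return max(counts, key=counts.get) if any(counts.values()) else ","


def read_occurrences(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> tuple[list[TaxonOccurrences], list[str]]:
    """Read a multi-taxon occurrence table.

    Parameters
    ----------
    path
        Delimited text file (UTF-8; comma/semicolon/tab auto-detected).
    column_map
        Mapping of logical field (``latitude``, ``longitude``, ``taxon``,
        optionally ``year``, ``higher_taxon``) to column name.  Defaults to
        ``ddlat`` / ``ddlon`` / ``tax`` / ``year`` / ``higher_tax``.

    Returns
    -------
    (taxa, warnings)
        Taxa in first-appearance order; one warning per dropped row.

    Raises
    ------
    ValueError
        If a mandatory column is missing or the file has no data rows.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, encoding="utf-8")
    if df.empty:
        raise ValueError(f"occurrence file {path} contains no data rows")
    for logical in ("latitude", "longitude", "taxon"):
        if cols[logical] not in df.columns:
            raise ValueError(
                f"mandatory column {cols[logical]!r} (for {logical}) not found; "
                f"available columns: {list(df.columns)}"
            )

    warns: list[str] = []
    taxa: dict[str, TaxonOccurrences] = {}
    has_year = cols["year"] in df.columns
    has_higher = cols["higher_taxon"] in df.columns

    for i, row in df.iterrows():
        taxon = str(row[cols["taxon"]]).strip() if pd.notna(row[cols["taxon"]]) else ""
        if not taxon or taxon.lower() == "nan":
            warns.append(f"row {i}: empty taxon name, row dropped")
            continue
        occ = taxa.setdefault(taxon, TaxonOccurrences(taxon))
        try:
            lat = float(row[cols["latitude"]])
            lon = float(row[cols["longitude"]])
        except (TypeError, ValueError):
            warns.append(f"row {i} ({taxon}): unparseable coordinates, row dropped")
            continue
        if not (np.isfinite(lat) and np.isfinite(lon)):
            warns.append(f"row {i} ({taxon}): non-finite coordinates, row dropped")
            continue
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            warns.append(
                f"row {i} ({taxon}): coordinates ({lat}, {lon}) outside WGS84 "
                "bounds, row dropped"
            )
            continue
        year: int | None = None
        if has_year and pd.notna(row[cols["year"]]):
            try:
                year = int(float(row[cols["year"]]))
            except (TypeError, ValueError):
                year = None
        higher = None
        if has_higher and pd.notna(row[cols["higher_taxon"]]):
            higher = str(row[cols["higher_taxon"]]).strip() or None
        occ.records.append(OccurrenceRecord(taxon, lat, lon, year, higher))

    return list(taxa.values()), warns


def taxa_from_frame(df: pd.DataFrame, column_map: dict[str, str] | None = None) -> list[TaxonOccurrences]:
    """Group an in-memory occurrence table (already validated coordinates)
    into :class:`TaxonOccurrences`, e.g. for synthetic data."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    taxa: dict[str, TaxonOccurrences] = {}
    has_year = cols["year"] in df.columns
    for _, row in df.iterrows():
        taxon = str(row[cols["taxon"]]).strip()
        occ = taxa.setdefault(taxon, TaxonOccurrences(taxon))
        year = None
        if has_year and pd.notna(row[cols["year"]]):
            year = int(row[cols["year"]])
        occ.records.append(
            OccurrenceRecord(taxon, float(row[cols["latitude"]]),
                             float(row[cols["longitude"]]), year)
        )
    return list(taxa.values())


def occurrences_to_frame(taxa: list[TaxonOccurrences]) -> pd.DataFrame:
    """Canonical tabular form of accepted records (round-trips through
    :func:`read_occurrences`)."""
    rows = []
    for t in taxa:
        for r in t.records:
            rows.append(
                {"ddlat": r.latitude, "ddlon": r.longitude, "tax": r.taxon,
                 "year": r.year, "higher_tax": r.higher_taxon}
            )
    return pd.DataFrame(rows, columns=["ddlat", "ddlon", "tax", "year", "higher_tax"])


def read_polygons(path: str | Path) -> tuple[ProtectedAreaSet, list[str]]:
    """Read a GeoJSON polygon layer (WGS84) into a :class:`ProtectedAreaSet`.

    Feature ids come from the feature ``id`` or an ``id``/``name`` property,
    falling back to the feature index.  Invalid rings are repaired with a
    warning; non-polygon geometry types raise.
    """
    path = Path(path)
    if path.suffix.lower() in {".shp", ".shx", ".dbf"}:
        raise ValueError(
            "shapefile input is not supported; convert to GeoJSON (e.g. "
            "`ogr2ogr -f GeoJSON out.geojson in.shp`)"
        )
    try:
        gj = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as e:
        raise ValueError(f"cannot read polygon file {path}: {e}") from e

    if gj.get("type") == "FeatureCollection":
        features = gj.get("features", [])
    elif gj.get("type") == "Feature":
        features = [gj]
    else:  # bare geometry
        features = [{"type": "Feature", "geometry": gj, "properties": {}}]

    warns: list[str] = []
    areas: list[tuple[str, Polygon | MultiPolygon]] = []
    if not features:
        warns.append(f"{path.name}: empty feature collection")
    seen_ids: set[str] = set()
    for idx, feat in enumerate(features):
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"{path.name} feature {idx}: geometry type {geom.geom_type} is "
                "not a polygon"
            )
        if not geom.is_valid:
            geom = make_valid(geom)
            # make_valid may return a collection; keep the areal parts
            if geom.geom_type == "GeometryCollection":
                polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
                geom = MultiPolygon(
                    [p for g in polys for p in (g.geoms if g.geom_type == "MultiPolygon" else [g])]
                )
            warns.append(f"{path.name} feature {idx}: invalid ring repaired")
        props = feat.get("properties") or {}
        pa_id = str(feat.get("id") or props.get("id") or props.get("name") or f"pa_{idx}")
        while pa_id in seen_ids:
            pa_id = f"{pa_id}_{idx}"
        seen_ids.add(pa_id)
        areas.append((pa_id, geom))
    return ProtectedAreaSet(areas), warns
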