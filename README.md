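# critb

Batch **preliminary IUCN Red List assessments under criterion B** from
georeferenced occurrence data.

Full Red List assessments are slow, expert-driven, taxon-by-taxon work;
meanwhile occurrence data (herbarium and museum records, GBIF downloads)
exist for hundreds of thousands of species.  `critb` computes, for every
taxon in a multi-species occurrence table, the geographic-range parameters
criterion B is built on and turns them into preliminary threat categories —
a triage tool for conservation practitioners and taxonomists, not a
replacement for full assessments.

## What it computes

For each taxon with occurrences (lat, lon in decimal degrees, WGS84):

- **EOO** (extent of occurrence, subcriterion B1): area of the minimum
  convex polygon — or optionally an alpha hull (Delaunay triangles with
  circumradius ≤ α) — in km² on an equal-area projection.  Fewer than three
  unique points → `NA`; exactly collinear points → the segment dilated by a
  0.1° buffer; EOO smaller than AOO → EOO is set equal to AOO.
- **AOO** (area of occupancy, subcriterion B2): number of occupied grid
  cells × cell area, 2 × 2 km cells by default, with the grid origin
  translated to minimise the count.
- **Number of locations** (condition a): occupied cells of a coarser grid
  (10 km side by default, or a sliding scale = 5% of the maximum
  interoccurrence distance), origin-minimised.  Protected-area (PA)
  polygons modify the count: under `no_more_than_one` every occupied PA is
  a single location; under `other` locations inside and outside PAs are
  counted separately.
- **Number of subpopulations**: unique occurrences buffered by circles of
  fixed radius (5 km default); overlapping circles merge into one
  subpopulation.

Categories follow the criterion-B rule: a subcriterion supports CR/EN/VU
only if both its range threshold (EOO < 100 / 5,000 / 20,000 km²; AOO < 10 /
500 / 2,000 km²) and the locations condition (≤ 1 / 5 / 10) are met at that
level, so each subcriterion's category is the *less* severe of its range
rank and the locations rank, and the final category is the *more* severe of
B1 and B2.  Continuing decline in habitat quality (condition b(iii)) is
assumed for every taxon and recorded in the output.  NT and LC are not
separated (reported as "NT or LC").

## Worked example

```python
from critb.synthetic import ScenarioSpec, generate_occurrences
from critb.occ_io import taxa_from_frame
from critb.assess import assess_batch

df, _ = generate_occurrences(ScenarioSpec(seed=42, n_taxa=3, clusters_per_taxon=2,
                                          points_per_cluster=8, cluster_spread_km=60.0))
_, table = assess_batch(taxa_from_frame(df))
print(table[["taxon", "n_unique_occurrences", "eoo_km2", "aoo_km2", "n_locations",
             "n_subpopulations", "final_category", "criterion_code"]].to_string(index=False))
```

```
    taxon  n_unique_occurrences  eoo_km2  aoo_km2  n_locations  n_subpopulations final_category criterion_code
Taxon_000                    16  311.962     36.0            2                 2             EN        B1a+B2a
Taxon_001                    16  297.144     36.0            2                 2             EN        B1a+B2a
Taxon_002                    16  311.762     44.0            2                 2             EN        B1a+B2a
```

Each synthetic taxon here has two point clusters about 60 km apart: hull
areas of ~300 km² (EN-level EOO), 9–11 occupied 2-km cells (EN-level AOO),
and 2 locations on the 10-km grid (EN level, ≤ 5), so both subcriteria
support EN and the code is `B1a+B2a`.

From the shell, on your own files:

```bash
critb assess --occurrences occ.csv --out run/ \
      --protected-areas pas.geojson --pa-method no_more_than_one \
      --draw-maps --grid-summary-deg 0.5
```

writes `run/results.csv` (one row per taxon), `run/run_metadata.json`
(config, thresholds, earth model), `run/geometries.geojson` (hulls, location
cells, subpopulation buffers), per-taxon PNG maps and a gridded
threatened-proportion summary.

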