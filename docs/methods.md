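# Methods

## Scope and model

`critb` automates the *geographic-range* part of IUCN Red List criterion B:
subcriterion B1 (extent of occurrence, EOO), subcriterion B2 (area of
occupancy, AOO), and condition (a) via an estimate of the number of
locations, plus a subpopulation count that the submission process asks for
but criterion B does not use directly.  Condition b(iii) — continuing
decline in habitat quality — is assumed true for every taxon; this is the
single modelling assumption that makes unattended batch assessment possible,
and it is written into every result row rather than silently applied.
Conditions b(i, ii, iv, v), c(i–iv), the "severely fragmented" alternative
to locations, and criteria A/C/D/E are out of scope: they require
taxon-specific information the input data do not carry.  Consequently the
output is a *preliminary* category, suitable for triage and as a starting
point for a full assessment.

## Geometry

All distances and areas are computed on a sphere of authalic radius
6371.0072 km (the sphere with the WGS84 ellipsoid's surface area).
Per-taxon computations run in a Lambert azimuthal equal-area projection
centred on the mean coordinate of the taxon's unique points.  Equal-area is
the property that matters: the IUCN thresholds test areas, and an equal-area
frame reports exactly the quantity thresholded regardless of where the range
sits.  Distance distortion of this projection is negligible at single-taxon
extents (sub-0.1% within ~1,000 km of the centre) and is covered by
round-trip and oracle tests.  The sphere-vs-ellipsoid choice can in
principle flip a category for a taxon whose metric sits within ~0.1% of a
threshold; the earth model is therefore recorded in the run metadata rather
than hidden.

Taxa spanning more than 120° of longitude are assessed but flagged
"projection unreliable"; taxa whose longitudes span more than 180° are
refused per-taxon with a warning (a single local frame cannot represent an
antimeridian-crossing range), without aborting the batch.

## EOO

Default hull is the minimum convex polygon of the planar points, mapped back
to WGS84 for output.  The alpha hull (union of Delaunay triangles with
circumradius ≤ α) is available for strongly concave or disjunct ranges; α is
a *length* in km (default 50 km) because a length threshold is reproducible
and directly interpretable, unlike the dimensionless multipliers some
implementations use.  Disjoint alpha-hull parts are summed with a warning
that this deviates from the strict single-boundary EOO definition; any
threshold-sensitive decision should use the convex hull as the primary
value.  As α → ∞ the alpha hull converges to the convex hull; agreement is
to ~0.1% rather than machine precision because near-collinear boundary
triangles have unbounded circumradii.

Degenerate cases: fewer than three unique occurrences → EOO undefined
(`NA`), and B1 is "not evaluated" downstream.  Exactly collinear points
would give a zero-area hull, so the segment is dilated by 0.1° (configurable)
in degree space and that polygon's equal-area km² is reported.  Collinearity
is detected when the smallest singular value of the centred planar
coordinate matrix is below 1e−6 km; points exactly collinear in *degree*
space trigger the same path, because the projection bends off-centre lines
by slightly more than the km tolerance.  Cropping polygons (e.g. sea masks)
are subtracted from the hull before area computation, always with a warning:
the practice is explicitly discouraged by the IUCN guidelines.  If the
resulting EOO is smaller than the AOO, the EOO is set equal to the AOO
before ranking (the orchestration layer applies this, since it is the only
place both values exist).

## AOO and locations

Both are occupied-cell counts of a square grid in the planar frame, with
cell *side lengths* in km: AOO default 2 km (the IUCN 2 × 2 km convention),
locations default 10 km.  A phrase like "a cell size of 10 km²" conflates
side and area; side-length is the interpretation used consistently here.
Because the count depends on grid placement, the origin is translated over
`origin_shifts` × `origin_shifts` evenly spaced offsets per axis (default 4,
always including (0, 0)) and the minimum count is reported — for both AOO
and locations, for consistency, since both are placement-sensitive.  Ties
take the first minimal offset in row-major scan order; cell membership is
half-open (floor((coord − offset)/side)), so boundary points land in the
larger-index cell.  Both conventions are arbitrary but deterministic, and
are pinned by tests.  With the default four shifts the count is an upper
bound on the global minimum over continuous offsets; the acceptance suite
verifies exact agreement with an exhaustive 0.01-km offset-lattice search
when the implementation scans that same lattice, and the bound otherwise.

The sliding-scale option sets the locations cell side to a fraction
(default 0.05) of the maximum pairwise great-circle distance, falling back
to the fixed default with a warning when that distance is zero.  It applies
to locations only, never AOO.

Protected areas modify the locations count.  Under `no_more_than_one`, each
PA containing at least one occurrence contributes exactly one location
(identity by PA polygon id, so two disjoint PAs holding points are two
locations) and the grid runs on the outside points only.  Under `other`,
the grid runs independently on inside-PA and outside-PA points and the
counts are summed, so a pair of points closer than one cell but straddling
a PA boundary is two locations.  Points exactly on a PA boundary count as
inside — the conservative (fewer-locations) convention.

## Subpopulations

Unique occurrences are buffered by circles of fixed radius (default 5 km,
exposed and recorded in metadata; no canonical default exists) and
overlapping circles merge.  Equal circles overlap iff centres are closer
than 2r, so the count is computed exactly as connected components of the
centre-distance graph; circle-union polygons are built only for maps.
Tangent circles (distance exactly 2r) do not merge.  The method ignores
taxon-specific dispersal ability by construction; the radius is the only
knob.

## Categorisation

Thresholds (EOO km² CR < 100, EN < 5,000, VU < 20,000; AOO km² CR < 10,
EN < 500, VU < 2,000; locations CR ≤ 1, EN ≤ 5, VU ≤ 10) live in one
editable `ThresholdTable`, echoed into every output; areas use strict `<`
("less than"), locations `≤` ("no more than").  A subcriterion's category is
the less severe of its range rank and the locations rank — both the
threshold and condition (a) must be met at a level for that level to hold —
and the final category is the more severe of the evaluated subcriteria.
The criterion code (`B1a`, `B2a`, `B1a+B2a`) names exactly the subcriteria
achieving the final category.  B1 is "not evaluated" when EOO is undefined.
NT and LC are not distinguished; no DD category is emitted — a taxon with
zero valid records yields a not-assessable `NA` row instead, since a
data-deficiency judgment needs information the tool does not model.

## Synthetic data

The generator emulates the structure of real multi-taxon compilations:
several taxa, each drawn as isotropic Gaussian clusters (per-cluster sd in
km) around uniformly placed centres in a square region, optionally with a
mosaic of disjoint rectangular protected areas covering a target fraction of
the region, and optional collection years.  All randomness flows through
one seeded NumPy generator; a fixed seed reproduces the table exactly.
Presets pin the degenerate regimes: `single_record` (EOO-undefined path),
`collinear` (three points on one meridian, segment-buffer path),
`narrow_endemic` (one 1-km-sd cluster of 30 points — CR regime),
`widespread` (12 clusters over ~1,500 km — NT/LC regime), and `pa_split`
(PA mosaic over a moderately spread taxon).

What the generator does *not* emulate: spatial autocorrelation beyond
clustering, coastlines and habitat masks, georeferencing error, taxonomic
noise, or collection-effort bias.  Passing tests therefore demonstrate
correctness of the geometry and the rule engine under known ground truth —
not robustness to the data-quality problems of real occurrence datasets,
which should be cleaned with dedicated tools before assessment.

## Numerical choices and problem sizes

Deduplication compares coordinates at full float precision (no rounding
rule exists that would not silently merge nearby points).  The oracle
comparisons in the acceptance suite use 200 random point sets of ≤ 8 points
against an exhaustive 0.01-km offset lattice and an independent
gift-wrapping hull; category recovery uses 100 seeds per preset and a
50-taxon batch — sizes chosen so the whole suite runs in well under a
minute per property while exercising every branch.

## Known limitations

- Preliminary categories only; condition b(iii) is assumed, never inferred.
- Antimeridian-crossing ranges are refused per-taxon, not handled.
- The locations estimator is a spatial proxy for a threat-based concept;
  where real threats operate at other scales, the cell side (or sliding
  fraction) must be chosen accordingly.
- Widespread but sparsely collected taxa can be over-flagged as threatened
  (few records → few locations); this is a property of the method, visible
  in the per-taxon warnings and record counts.
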