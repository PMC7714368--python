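# Methods

## Model and procedure

`nrassess` assesses, for each (species, focal area) pair, how much
responsibility the focal area carries for conserving the species, and
how urgent that responsibility is given the species' global threat
status. The procedure is a deterministic polygon-overlay pipeline:

1. **Validation.** All layers must share a coordinate reference system
   (identical, or all geographic on the same datum). Every focal area
   must lie inside the reference area up to sliver tolerance. Species
   ranges extending beyond the reference are clipped with a warning
   (default) or rejected (strict policy); the fraction retained is
   reported as the containment ratio.
2. **Pattern.** The within-reference range is overlaid on the
   biogeographical units. The Polygon Count-Approach classifies by the
   number of occupied units; the Polygon Area-Approach by the largest
   per-unit share of the range area. Pattern is a property of the
   species (computed once against the reference), not of a focal area.
3. **Proportions.** `DP_exp` is the share of the reference area the
   range covers; `DP_obs` is the share of each focal area it covers.
   Both are clamped to [0, 1] to absorb overlay round-off at the
   1e-12 level.
4. **Responsibility.** A 3 × 2 table maps (pattern, DP_obs higher than
   DP_exp?) to a class: wide → Basic/Medium, regional → Medium/High,
   local → High/Very high. Species absent from a focal area get None.
5. **Priority.** Responsibility is crossed with the global IUCN Red
   List category through a fixed 6 × 4 matrix of (class, score) pairs.
   The matrix is irregular expert-assigned data: it is shipped as a
   checksummed literal, never derived from a formula. DD/NE species
   and None-responsibility pairs are "not evaluable".

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pc_local_max` | 1 | PC-A: at most this many units → local |
| `pc_regional_max` | 3 | PC-A: up to this many units → regional |
| `pa_regional_fraction` | 2/3 | PA-A: minimum single-unit share for regional (inclusive) |
| `strict_comparison` | true | `DP_obs > DP_exp`; ties resolve downward |
| `area_mode` | auto | geodesic for geographic CRS, planar for projected |
| `sliver_tolerance` | 1e-9 | fraction of the reference area treated as zero overlap |
| `containment_policy` | warn_and_clip | clip out-of-reference ranges vs reject |

The count thresholds are the method's conventional setting and are
deliberately configurable: unit counts can mislead where environmental
conditions change rapidly over space, which is also why the area-based
alternative exists. The responsibility table is likewise configuration
data; any override is validated for monotonicity in both arguments
(more over-representation or a narrower pattern can never lower the
class) and printed in every output summary, so no run's class borders
are implicit.

Design choices made where the design was genuinely open:

* **Ties are not over-representation.** `DP_obs = DP_exp` carries no
  evidence that a country holds more than its size predicts, so the
  strict comparison is the default and ties take the lower branch.
* **The 2/3 boundary is regional.** A range with exactly two-thirds of
  its area in one unit *is* concentrated in that unit; the bound is
  inclusive.
* **PA-A local criterion.** The area approach calls a range local only
  when it occupies a single unit; a dominant share spread over two
  units is regional, not local.
* **Presence needs more than a sliver.** A species is present in a
  focal area only when the overlap exceeds the sliver tolerance, so
  boundary artifacts cannot create responsibilities.
* **Overlapping units.** Biogeographical zonations are partitions;
  overlaps above tolerance are counted toward every overlapping unit
  (and signal defective input rather than a modelling choice).

## Numerical choices

* **Areas** are km². Planar areas come from the exact vector shoelace
  computation in the CRS unit. Geographic areas are spherical polygon
  areas on the WGS84 authalic sphere (radius 6371.0071809184 km),
  computed by the Chamberlain–Duquette line integral; for
  longitude/latitude-aligned rectangles this is exactly the closed
  form `R²·Δλ·(sin φ₂ − sin φ₁)`, and for the sub-10° polygons this
  tool handles the sphere-vs-ellipsoid difference is orders of
  magnitude below the 0.5 % agreement the tests demand. The tool never
  reprojects: the area mode selects an algorithm, not a CRS.
* **Geometry repair.** Invalid polygons (self-intersections are common
  in real range files) are repaired on read with a make-valid step and
  counted; irreparable features abort the read rather than silently
  biasing areas.
* **Quartiles** in the approach comparison use inclusive linear
  interpolation over the pooled per-country counts of both approaches;
  country ranks are by descending count with ties broken by focal-area
  id. Both rules are deterministic and documented here rather than
  guessed from any particular published rounding.
* **dBase output** uses dBase III with field names truncated to 10
  characters by a deterministic rule; the long-to-short mapping is
  printed in the run summary.

## The synthetic world

The generator builds a 100 × 100 km planar reference square tiled by
`n_countries` vertical country strips and `n_units` horizontal unit
strips, with four archetype ranges: an endemic confined to one country
and one unit; a compact regional range spanning two countries with 70 %
of its area in one unit; a disjunct pair of equal patches in different
countries and units (regional by count, wide by area — the archetype
that separates the two approaches); and a widespread range covering
every country in exact proportion to its size, which pins the
tie-handling of the DP comparison. Default IUCN categories
(EN, VU, NT, LC) exercise the interesting rows of the priority matrix.

Every expected value — areas, occupancies, proportions, patterns,
classes, scores — is recomputed from the generated coordinates by pure
rectangle interval arithmetic, independent of the geometry library, so
the overlay pipeline is tested against closed-form truth. A raster
counting oracle (cell centers inside the polygon, error bounded by
perimeter × cell size) provides a second independent check for
arbitrary shapes, and the spherical closed form above checks the
geodesic path.

What the toy world does **not** emulate: real range maps are not
rectangles — they have holes, slivers, shared borders, and invalid
rings; real zonations are not equal strips; real countries do not tile
the reference exactly; and geographic data make every area computation
approximate. Passing tests therefore demonstrate the correctness of
the overlay arithmetic, the classification rules and the bookkeeping —
not the ecological adequacy of any particular zonation or range
dataset. Problem sizes in the tests and the acceptance script (a
4 × 5 toy grid, 20 random convex polygons at 0.02 km oracle cells) are
chosen so the whole suite completes in seconds while keeping the
oracle error an order of magnitude below the tolerances checked.

## Degenerate inputs

A zero-area reference or focal feature is an error. A species with no
range inside the reference area cannot be patterned: it is reported
with a warning, `DP` values of zero, and None responsibility
everywhere. An empty species set yields an empty run with a warning.
Species named in the metadata without a range layer are listed as
missing; range layers without metadata are assessed for responsibility
with priority marked not evaluable.

## Limitations

* Vector I/O is GeoJSON only; Shapefile/GeoPackage inputs must be
  converted first (the error message shows the one-line `ogr2ogr`
  incantation).
* Geographic overlays intersect geometries in longitude/latitude space
  before measuring spherically — standard practice, accurate for the
  regional extents this tool targets, but not a substitute for an
  equal-area projection in continental-scale area-critical work.
* Range extent is the only signal: no abundance weighting, no
  population viability, no national red-list status.
* Only polygon inputs are supported; raster distributions must be
  vectorized upstream.
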