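"""Deterministic synthetic worlds with analytically known truths.

A toy world is a 100 x 100 km planar reference square, tiled exactly by
``n_countries`` vertical country strips and overlaid by ``n_units``
horizontal biogeographical-unit strips. Four archetype species ranges
mirror the classic range types used to illustrate responsibility
assessments:

* ``endemic`` — a single rectangle inside one country and one unit
  (the island-endemic shrew archetype),
* ``regional_closed`` — a compact range spanning two countries with
  70% of its area in one unit (above the two-thirds regional fraction
  of the area approach),
* ``disjunct`` — two separated equal patches in different countries
  and units,
* ``widespread`` — a range covering every country and every unit.

Every expected value (areas, proportions, occupancy, patterns and
classes under the default configuration) is computed by closed-form
rectangle interval arithmetic — pure Python, no geometry library — so
the overlay pipeline can be checked against an independent source of
truth. Placement of the endemic, regional_closed and disjunct
rectangles is jittered by the seed inside their host cells; the unit
shares and country spans that define each archetype are preserved.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .core_model import (
    AssessmentConfig,
    DistributionPattern,
    IUCNCategory,
    ResponsibilityClass,
    validate_config,
)
from .geo_io import (
    Feature,
    LayerRole,
    LayerSet,
    PolygonLayer,
    PLANAR_KM,
    AUTHALIC_RADIUS_KM,
    write_layer,
)

WORLD_SIZE_KM = 100.0

ARCHETYPE_IUCN = {
    "endemic": IUCNCategory.EN,
    "regional_closed": IUCNCategory.VU,
    "disjunct": IUCNCategory.NT,
    "widespread": IUCNCategory.LC,
}

Rect = tuple[float, float, float, float]  # x0, x1, y0, y1


# --- independent rectangle arithmetic (no geometry library) ----------------


def _rect_area(r: Rect) -> float:
    return max(0.0, r[1] - r[0]) * max(0.0, r[3] - r[2])


def _rect_intersection_area(a: Rect, b: Rect) -> float:
    w = min(a[1], b[1]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[2], b[2])
    return max(0.0, w) * max(0.0, h)


def _rects_area(rects: list[Rect]) -> float:
    # archetype patches are disjoint by construction
    return sum(_rect_area(r) for r in rects)


def _rects_overlap(rects: list[Rect], other: Rect) -> float:
    return sum(_rect_intersection_area(r, other) for r in rects)


def spherical_rect_area_km2(lon0: float, lon1: float, lat0: float, lat1: float) -> float:
    """Closed-form spherical area of a lon/lat rectangle, km².

    A = R² · Δλ · (sin φ₂ − sin φ₁) on the authalic sphere; serves as
    the independent oracle for geodesic polygon areas.
    """
    R = AUTHALIC_RADIUS_KM
    dlon = np.radians(lon1 - lon0)
    return R * R * dlon * (np.sin(np.radians(lat1)) - np.sin(np.radians(lat0)))


def raster_oracle_area(geometry: BaseGeometry, cell_km: float) -> float:
    """Brute-force area by counting raster cell centers inside the geometry.

    Error is bounded by O(perimeter x cell size); independent of the
    polygon-area code path (point-in-polygon tests only).
    """
    if cell_km <= 0:
        raise ValueError("cell size must be positive")
    if geometry.is_empty:
        return 0.0
    minx, miny, maxx, maxy = geometry.bounds
    xs = np.arange(minx + cell_km / 2.0, maxx, cell_km)
    ys = np.arange(miny + cell_km / 2.0, maxy, cell_km)
    if xs.size == 0 or ys.size == 0:
        return 0.0
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geometry, gx.ravel(), gy.ravel())
    return float(inside.sum()) * cell_km * cell_km


# --- toy world -------------------------------------------------------------


@dataclass
class ToyWorld:
    seed: int
    n_countries: int
    n_units: int
    reference: Rect
    countries: dict[str, Rect]
    units: dict[str, Rect]
    unit_realm: dict[str, str]  # higher-level attribute for dissolve
    species: dict[str, list[Rect]]
    iucn: dict[str, IUCNCategory]
    expected: dict = field(default_factory=dict)

    def to_layerset(self) -> LayerSet:
        """Build in-memory polygon layers (planar km CRS) from the rectangles."""

        def poly(r: Rect):
            return box(r[0], r[2], r[1], r[3])

        species_layers = [
            PolygonLayer(
                LayerRole.SPECIES,
                [
                    Feature(
                        sid,
                        shapely.union_all([poly(r) for r in rects]),
                        {"species_id": sid},
                    )
                ],
                PLANAR_KM,
            )
            for sid, rects in self.species.items()
        ]
        units = PolygonLayer(
            LayerRole.UNITS,
            [
                Feature(uid, poly(r), {"unit_id": uid, "realm": self.unit_realm[uid]})
                for uid, r in self.units.items()
            ],
            PLANAR_KM,
        )
        focal = PolygonLayer(
            LayerRole.FOCAL,
            [Feature(cid, poly(r), {"country": cid}) for cid, r in self.countries.items()],
            PLANAR_KM,
        )
        reference = PolygonLayer(
            LayerRole.REFERENCE,
            [Feature("reference", poly(self.reference), {"name": "toy reference"})],
            PLANAR_KM,
        )
        return LayerSet(species_layers, units, focal, reference)


def _expected_pattern(n_units: int, p_max: float, cfg: AssessmentConfig):
    """Apply the documented default thresholds to closed-form occupancy."""
    if n_units <= cfg.pc_local_max:
        pc = DistributionPattern.LOCAL
    elif n_units <= cfg.pc_regional_max:
        pc = DistributionPattern.REGIONAL
    else:
        pc = DistributionPattern.WIDE
    if n_units == 1:
        pa = DistributionPattern.LOCAL
    elif p_max >= cfg.pa_regional_fraction:
        pa = DistributionPattern.REGIONAL
    else:
        pa = DistributionPattern.WIDE
    return pc, pa


def make_toy_world(seed: int = 0, n_countries: int = 4, n_units: int = 5) -> ToyWorld:
    """Construct a deterministic toy world with closed-form expected truths."""
    if n_countries < 2 or n_units < 2:
        raise ValueError("toy world needs at least 2 countries and 2 units")
    W = H = WORLD_SIZE_KM
    cw, uh = W / n_countries, H / n_units
    if cw < 4.0 or uh < 4.0:
        raise ValueError("grid too fine: country/unit strips narrower than 4 km")
    rng = np.random.default_rng(seed)

    reference: Rect = (0.0, W, 0.0, H)
    countries = {f"C{i+1}": (i * cw, (i + 1) * cw, 0.0, H) for i in range(n_countries)}
    units = {f"U{j+1}": (0.0, W, j * uh, (j + 1) * uh) for j in range(n_units)}
    unit_realm = {f"U{j+1}": ("R1" if j < n_units // 2 else "R2") for j in range(n_units)}

    # endemic: jittered rectangle inside country 1 x unit 1
    ew, eh = 0.5 * cw, 0.5 * uh
    ex = float(rng.uniform(0.05, 0.45)) * cw
    ey = float(rng.uniform(0.05, 0.45)) * uh
    endemic: list[Rect] = [(ex, ex + ew, ey, ey + eh)]

    # regional_closed: crosses the C1/C2 border; 70% of its area in unit 1
    # (y in [0.3*uh, uh]) and 30% in unit 2 (y in [uh, 1.3*uh]) — safely
    # above the 2/3 regional fraction without sitting on the boundary
    rx = float(rng.uniform(0.3, 0.7)) * cw
    regional_closed: list[Rect] = [(rx, rx + cw, 0.3 * uh, 1.3 * uh)]

    # disjunct: two equal jittered patches in distinct country x unit cells
    def _patch(ci: int, uj: int) -> Rect:
        px = (ci + float(rng.uniform(0.1, 0.5))) * cw
        py = (uj + float(rng.uniform(0.1, 0.5))) * uh
        return (px, px + 0.4 * cw, py, py + 0.4 * uh)

    disjunct = [_patch(n_countries - 2, n_units - 2), _patch(n_countries - 1, n_units - 1)]

    # widespread: all countries, all units (last unit half-covered)
    widespread: list[Rect] = [(0.0, W, 0.0, H - uh / 2.0)]

    species = {
        "endemic": endemic,
        "regional_closed": regional_closed,
        "disjunct": disjunct,
        "widespread": widespread,
    }
    world = ToyWorld(
        seed=seed,
        n_countries=n_countries,
        n_units=n_units,
        reference=reference,
        countries=countries,
        units=units,
        unit_realm=unit_realm,
        species=species,
        iucn=dict(ARCHETYPE_IUCN),
    )
    world.expected = _compute_expected(world)
    return world


def _compute_expected(world: ToyWorld) -> dict:
    """Closed-form truths under the default configuration."""
    from .priority import build_priority_matrix

    cfg = validate_config(AssessmentConfig())
    matrix = build_priority_matrix()
    ref_area = _rect_area(world.reference)
    exp: dict = {
        "area_reference": ref_area,
        "area_focal": {cid: _rect_area(r) for cid, r in world.countries.items()},
        "species_total_area": {},
        "dp_exp": {},
        "dp_obs": {},
        "occupancy": {},
        "pattern": {"count": {}, "area": {}},
        "nr": {"count": {}, "area": {}},
        "score": {"count": {}, "area": {}},
    }
    for sid, rects in world.species.items():
        total = _rects_area(rects)
        exp["species_total_area"][sid] = total
        dp_exp = total / ref_area  # all ranges lie inside the reference
        exp["dp_exp"][sid] = dp_exp
        per_unit = {
            uid: a
            for uid, r in world.units.items()
            if (a := _rects_overlap(rects, r)) > cfg.sliver_tolerance * ref_area
        }
        n_units = len(per_unit)
        p_max = max(per_unit.values()) / total
        exp["occupancy"][sid] = {"per_unit": per_unit, "n_units": n_units, "p_max": p_max}
        pc, pa = _expected_pattern(n_units, p_max, cfg)
        exp["pattern"]["count"][sid] = pc
        exp["pattern"]["area"][sid] = pa
        exp["dp_obs"][sid] = {}
        for approach, pattern in (("count", pc), ("area", pa)):
            exp["nr"][approach][sid] = {}
            exp["score"][approach][sid] = {}
        for cid, crect in world.countries.items():
            in_focal = _rects_overlap(rects, crect)
            dp_obs = in_focal / _rect_area(crect)
            exp["dp_obs"][sid][cid] = dp_obs
            present = in_focal > cfg.sliver_tolerance * ref_area
            higher = dp_obs > dp_exp  # strict default
            for approach, pattern in (("count", pc), ("area", pa)):
                nr = (
                    cfg.nr_mapping[(pattern, higher)]
                    if present
                    else ResponsibilityClass.NONE
                )
                exp["nr"][approach][sid][cid] = nr
                cat = world.iucn[sid]
                if nr is ResponsibilityClass.NONE or not cat.evaluable:
                    exp["score"][approach][sid][cid] = None
                else:
                    exp["score"][approach][sid][cid] = matrix.entry(cat, nr)
    return exp


def write_fixture_files(world: ToyWorld, out_dir) -> list[str]:
    """Write the toy world as convention-named GeoJSON layers plus metadata.

    Emits ``s-<archetype>.geojson`` per species, ``g-units.geojson``,
    ``g-reference.geojson``, ``f-countries.geojson``, a species metadata
    CSV, a semicolon-separated species list, and a manifest.
    """
    os.makedirs(out_dir, exist_ok=True)
    ls = world.to_layerset()
    manifest: list[str] = []

    def emit(layer, name):
        path = os.path.join(out_dir, name)
        write_layer(layer, path)
        manifest.append(path)

    for sp_layer in ls.species:
        emit(sp_layer, f"s-{sp_layer.features[0].feature_id}.geojson")
    emit(ls.units, "g-units.geojson")
    emit(ls.reference, "g-reference.geojson")
    emit(ls.focal, "f-countries.geojson")

    meta_path = os.path.join(out_dir, "species_metadata.csv")
    with open(meta_path, "w", encoding="utf-8") as fh:
        fh.write("species_id,iucn_category\n")
        for sid in world.species:
            fh.write(f"{sid},{world.iucn[sid].name}\n")
    manifest.append(meta_path)

    list_path = os.path.join(out_dir, "species_list.txt")
    with open(list_path, "w", encoding="utf-8") as fh:
        fh.write(";".join(world.species))
    manifest.append(list_path)

    man_path = os.path.join(out_dir, "manifest.txt")
    with open(man_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(os.path.basename(p) for p in manifest) + "\n")
    manifest.append(man_path)
    return manifest


def random_convex_polygons(seed: int, n: int, max_span_km: float = 50.0):
    """Seeded random convex polygons for oracle-agreement testing."""
    rng = np.random.default_rng(seed)
    polys = []
    for _ in range(n):
        k = int(rng.integers(5, 12))
        pts = rng.uniform(0.0, max_span_km, size=(k, 2))
        hull = shapely.MultiPoint(pts).convex_hull
        if hull.geom_type == "Polygon":
            polys.append(hull)
    return polys
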