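"""Vector-layer I/O, area computation, dissolve, and layer-set validation.

Layers are GeoJSON feature collections. The tool's file-naming
convention assigns roles by filename prefix: ``s-`` species range,
``g-`` biogeographical units or reference area, ``f-`` focal areas
(one polygon per administrative unit). Files outside the convention
are rejected unless an explicit role override is given.

Areas are reported in km². For projected (planar) coordinate systems
the area is the plane polygon area in the CRS unit; for geographic
coordinates it is the spherical polygon area on the WGS84 authalic
sphere, which agrees with ellipsoidal geodesic areas to well below a
tenth of a percent at the scales relevant here. The tool never
reprojects: the area mode selects an algorithm, not a new CRS.
"""

from __future__ import annotations

import enum
import json
import logging
import math
import os
from dataclasses import dataclass, field

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.validation import make_valid

from .core_model import (
    AssessmentConfig,
    AssessmentRecord,
    ContainmentPolicy,
    AreaMode,
)
from . import _dbf

logger = logging.getLogger("nrassess")

#: WGS84 authalic sphere radius, km (sphere with the ellipsoid's surface area)
AUTHALIC_RADIUS_KM = 6371.0071809184


class LayerRole(enum.Enum):
    SPECIES = "species"
    UNITS = "units"
    FOCAL = "focal"
    REFERENCE = "reference"


_PREFIX_ROLES = {"s-": LayerRole.SPECIES, "g-": LayerRole.UNITS, "f-": LayerRole.FOCAL}


@dataclass(frozen=True)
class CRS:
    """Light-weight coordinate-reference-system descriptor.

    ``geographic`` coordinates are longitude/latitude degrees;
    projected coordinates carry a linear ``unit`` ("km" or "m").
    """

    name: str
    geographic: bool
    unit: str = "degree"

    def compatible(self, other: "CRS") -> bool:
        if self.name == other.name:
            return True
        return self.geographic and other.geographic

    @property
    def planar_to_km2(self) -> float:
        if self.geographic:
            raise ValueError(f"{self.name} is geographic; planar area is undefined")
        return 1.0 if self.unit == "km" else 1e-6


WGS84 = CRS("EPSG:4326", geographic=True)
PLANAR_KM = CRS("LOCAL_KM", geographic=False, unit="km")
PLANAR_M = CRS("LOCAL_M", geographic=False, unit="m")

_KNOWN_CRS = {
    "EPSG:4326": WGS84,
    "URN:OGC:DEF:CRS:OGC:1.3:CRS84": WGS84,
    "CRS84": WGS84,
    "WGS84": WGS84,
    "LOCAL_KM": PLANAR_KM,
    "LOCAL_M": PLANAR_M,
}


def parse_crs(name: str | None) -> CRS | None:
    if name is None:
        return None
    crs = _KNOWN_CRS.get(name.strip().upper())
    if crs is None:
        raise ValueError(f"unrecognized coordinate reference system: {name!r}")
    return crs


@dataclass
class Feature:
    feature_id: str
    geometry: BaseGeometry
    attributes: dict = field(default_factory=dict)


@dataclass
class PolygonLayer:
    """A set of polygon features with a shared CRS and a declared role."""

    role: LayerRole
    features: list[Feature]
    crs: CRS | None
    source_path: str = "synthetic"
    repairs: int = 0  # geometries fixed on ingestion

    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def union(self) -> BaseGeometry:
        return unary_union([f.geometry for f in self.features])

    def get(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)


@dataclass
class LayerSet:
    species: list[PolygonLayer]
    units: PolygonLayer
    focal: PolygonLayer
    reference: PolygonLayer

    def all_layers(self) -> list[PolygonLayer]:
        return [*self.species, self.units, self.focal, self.reference]


def infer_role(path: str) -> LayerRole | None:
    base = os.path.basename(str(path))
    return _PREFIX_ROLES.get(base[:2])


def _repair(geom: BaseGeometry, feature_id: str, counter: list) -> BaseGeometry:
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    # make_valid may emit collections; keep the areal part only
    if fixed.geom_type == "GeometryCollection":
        polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        fixed = unary_union(polys) if polys else None
    if fixed is None or fixed.is_empty or not fixed.is_valid:
        raise ValueError(f"irreparable geometry in feature {feature_id!r}")
    counter[0] += 1
    logger.warning("repaired invalid geometry in feature %s", feature_id)
    return fixed


def _feature_id(props: dict, index: int) -> str:
    for key in ("id", "feature_id", "name", "unit_id", "species_id"):
        if key in props and props[key] not in (None, ""):
            return str(props[key])
    return str(index)


def read_layer(path, role_override: LayerRole | None = None) -> PolygonLayer:
    """Read a GeoJSON polygon layer, inferring its role from the filename.

    Filenames must follow the convention ``s-*`` (species), ``g-*``
    (units / reference), ``f-*`` (focal areas); otherwise an explicit
    ``role_override`` is required.
    """
    path = str(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".shp", ".gpkg"):
        raise ValueError(
            f"{path}: only GeoJSON layers are supported; convert Shapefile/GeoPackage "
            "inputs to GeoJSON (e.g. `ogr2ogr -f GeoJSON out.geojson in.shp`)"
        )
    role = role_override or infer_role(path)
    if role is None:
        raise ValueError(
            f"{path}: filename does not follow the s-/g-/f- naming convention "
            "and no role override was given"
        )
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    crs_name = None
    if isinstance(doc.get("crs"), dict):
        crs_name = doc["crs"].get("properties", {}).get("name")
    crs = parse_crs(crs_name)
    repairs = [0]
    feats: list[Feature] = []
    for i, f in enumerate(doc.get("features", [])):
        geom = shape(f["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"{path}: feature {i} is {geom.geom_type}; polygon layers only"
            )
        props = dict(f.get("properties") or {})
        fid = str(f["id"]) if "id" in f else _feature_id(props, i)
        feats.append(Feature(fid, _repair(geom, fid, repairs), props))
    layer = PolygonLayer(role, feats, crs, source_path=path, repairs=repairs[0])
    _check_layer_invariants(layer)
    return layer


def _check_layer_invariants(layer: PolygonLayer) -> None:
    if layer.role in (LayerRole.FOCAL, LayerRole.UNITS):
        ids = layer.feature_ids()
        if not ids:
            raise ValueError(f"{layer.role.value} layer must contain at least one feature")
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate feature ids in {layer.role.value} layer")


def write_layer(layer: PolygonLayer, path) -> None:
    """Write a layer as GeoJSON (with a legacy ``crs`` member)."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "id": f.feature_id,
                "properties": f.attributes,
                "geometry": mapping(f.geometry),
            }
            for f in layer.features
        ],
    }
    if layer.crs is not None:
        doc["crs"] = {"type": "name", "properties": {"name": layer.crs.name}}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")


# --- areas -----------------------------------------------------------------


def _spherical_ring_area_km2(coords) -> float:
    """Signed spherical area of a lon/lat ring (Chamberlain–Duquette)."""
    total = 0.0
    n = len(coords)
    for i in range(n - 1):
        lon1, lat1 = coords[i][0], coords[i][1]
        lon2, lat2 = coords[i + 1][0], coords[i + 1][1]
        total += math.radians(lon2 - lon1) * (
            2.0 + math.sin(math.radians(lat1)) + math.sin(math.radians(lat2))
        )
    return total * AUTHALIC_RADIUS_KM**2 / 2.0


def _spherical_area_km2(geom: BaseGeometry) -> float:
    if geom.is_empty:
        return 0.0
    if geom.geom_type == "Polygon":
        area = abs(_spherical_ring_area_km2(list(geom.exterior.coords)))
        for ring in geom.interiors:
            area -= abs(_spherical_ring_area_km2(list(ring.coords)))
        return max(area, 0.0)
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        return sum(_spherical_area_km2(g) for g in geom.geoms)
    return 0.0


def polygon_area(geom: BaseGeometry, crs: CRS | None, mode: AreaMode = AreaMode.AUTO) -> float:
    """Area of a polygon or multi-polygon in km².

    AUTO resolves to geodesic (spherical) area for geographic CRS and
    planar area for projected CRS; a missing CRS is an error because
    the unit of the coordinates is then unknown.
    """
    if geom is None or geom.is_empty:
        return 0.0
    if mode is AreaMode.AUTO:
        if crs is None:
            raise ValueError(
                "cannot choose an area algorithm: geodata should have a spatial reference"
            )
        mode = AreaMode.GEODESIC if crs.geographic else AreaMode.PLANAR
    if mode is AreaMode.GEODESIC:
        return _spherical_area_km2(geom)
    factor = crs.planar_to_km2 if crs is not None else 1.0
    return geom.area * factor


def dissolve_by_attribute(units: PolygonLayer, attr: str) -> PolygonLayer:
    """Merge features sharing an attribute value into single features.

    The grouped higher-level polygons can serve as a reference area
    built from biogeographical units.
    """
    groups: dict[str, list[BaseGeometry]] = {}
    for f in units.features:
        if attr not in f.attributes:
            raise ValueError(f"feature {f.feature_id!r} lacks attribute {attr!r}")
        groups.setdefault(str(f.attributes[attr]), []).append(f.geometry)
    feats = [
        Feature(value, unary_union(geoms), {attr: value})
        for value, geoms in sorted(groups.items())
    ]
    return PolygonLayer(units.role, feats, units.crs, source_path=units.source_path)


# --- layer-set validation --------------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of layer-set validation.

    ``layerset`` is the validated set; under the warn-and-clip policy,
    species layers extending beyond the reference area are replaced by
    their clipped counterparts.
    """

    layerset: LayerSet
    warnings: list[str] = field(default_factory=list)
    focal_contained: dict[str, bool] = field(default_factory=dict)
    containment_ratio: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(self.focal_contained.values())


def check_layerset(ls: LayerSet, cfg: AssessmentConfig) -> ValidationReport:
    """Validate CRS compatibility and containment in the reference area.

    Focal features must lie inside the reference area (up to sliver
    tolerance); species ranges extending beyond it are clipped with a
    warning, or rejected under the strict containment policy.
    """
    layers = ls.all_layers()
    base = next((l.crs for l in layers if l.crs is not None), None)
    for layer in layers:
        if layer.crs is None or base is None or not layer.crs.compatible(base):
            raise ValueError(
                "all input files of one assessment should use the same "
                f"coordinate reference / projection system (offending layer: {layer.source_path})"
            )
    mode = cfg.area_mode
    ref_geom = ls.reference.union()
    ref_area = polygon_area(ref_geom, ls.reference.crs, mode)
    if ref_area <= 0:
        raise ValueError("reference area has zero area")
    tol = cfg.sliver_tolerance * ref_area

    report = ValidationReport(layerset=ls)
    for f in ls.focal.features:
        outside = polygon_area(f.geometry.difference(ref_geom), ls.focal.crs, mode)
        contained = outside <= tol
        report.focal_contained[f.feature_id] = contained
        if not contained:
            report.warnings.append(
                f"focal area {f.feature_id!r} is not completely enclosed by the "
                f"reference area ({outside:.6g} km² outside)"
            )

    clipped_species: list[PolygonLayer] = []
    for sp in ls.species:
        total = polygon_area(sp.union(), sp.crs, mode)
        inside_geom = sp.union().intersection(ref_geom)
        inside = polygon_area(inside_geom, sp.crs, mode)
        ratio = 1.0 if total == 0 else min(inside / total, 1.0)
        sid = sp.features[0].feature_id if sp.features else sp.source_path
        report.containment_ratio[sid] = ratio
        if total - inside > tol:
            msg = (
                f"species {sid!r} extends beyond the reference area "
                f"(containment ratio {ratio:.4f})"
            )
            if cfg.containment_policy is ContainmentPolicy.ERROR:
                raise ValueError(msg)
            report.warnings.append(msg + "; clipped to the reference area")
            logger.warning("%s", msg)
            sp = PolygonLayer(
                sp.role,
                [Feature(sid, inside_geom, dict(sp.features[0].attributes))],
                sp.crs,
                source_path=sp.source_path,
                repairs=sp.repairs,
            )
        clipped_species.append(sp)
    report.layerset = LayerSet(clipped_species, ls.units, ls.focal, ls.reference)
    return report


# --- outputs ---------------------------------------------------------------

_TABLE_COLUMNS = [
    "species_id",
    "focal_id",
    "area_reference",
    "area_focal",
    "area_dist_in_reference",
    "area_dist_in_focal",
    "dp_exp",
    "dp_obs",
    "n_units",
    "p_max",
    "pattern",
    "nr",
    "cp_class",
    "score",
    "containment_ratio",
]


def _record_row(r: AssessmentRecord) -> dict:
    return {
        "species_id": r.species_id,
        "focal_id": r.focal_id,
        "area_reference": r.area_reference,
        "area_focal": r.area_focal,
        "area_dist_in_reference": r.area_dist_in_reference,
        "area_dist_in_focal": r.area_dist_in_focal,
        "dp_exp": r.dp_exp,
        "dp_obs": r.dp_obs,
        "n_units": r.n_units,
        "p_max": r.p_max,
        "pattern": r.pattern.value if r.pattern else "",
        "nr": r.nr.label,
        "cp_class": r.priority.cp_class if r.priority.evaluable else "",
        "score": r.priority.score if r.priority.evaluable else "",
        "containment_ratio": r.containment_ratio,
    }


def write_outputs(
    records: list[AssessmentRecord],
    focal: PolygonLayer,
    out_dir,
    formats: set[str] | None = None,
    cfg: AssessmentConfig | None = None,
    warnings: list[str] | None = None,
) -> list[str]:
    """Write maps, attribute tables and the ASCII summary; returns the manifest.

    Products: per-species GeoJSON map layers joining the focal polygons
    with the assessment attributes; a flat attribute table as CSV and
    dBase III (.dbf, field names truncated to 10 characters); and a
    plain-text summary of configuration, thresholds and per-species
    per-country classes.
    """
    import pandas as pd

    if not records:
        raise ValueError("no assessment records to write")
    formats = formats or {"geojson", "csv", "dbf", "summary"}
    os.makedirs(out_dir, exist_ok=True)
    manifest: list[str] = []
    rows = [_record_row(r) for r in records]
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)

    if "geojson" in formats:
        by_species: dict[str, dict[str, dict]] = {}
        for row in rows:
            by_species.setdefault(row["species_id"], {})[row["focal_id"]] = row
        for sid, per_focal in by_species.items():
            feats = []
            for f in focal.features:
                attrs = dict(f.attributes)
                row = per_focal.get(f.feature_id)
                if row:
                    attrs.update(
                        {
                            k: row[k]
                            for k in ("dp_exp", "dp_obs", "pattern", "nr", "cp_class", "score")
                        }
                    )
                feats.append(Feature(f.feature_id, f.geometry, attrs))
            path = os.path.join(out_dir, f"map_{sid}.geojson")
            write_layer(PolygonLayer(LayerRole.FOCAL, feats, focal.crs), path)
            manifest.append(path)

    if "csv" in formats:
        path = os.path.join(out_dir, "results.csv")
        df.to_csv(path, index=False)
        manifest.append(path)

    name_map = _dbf.truncate_field_names(_TABLE_COLUMNS)
    if "dbf" in formats:
        fields = []
        for col in _TABLE_COLUMNS:
            short = name_map[col]
            if col in ("species_id", "focal_id", "pattern", "nr"):
                width = max([len(str(r[col])) for r in rows] + [4])
                fields.append(_dbf.DbfField(short, "C", min(width, 64)))
            elif col in ("n_units", "cp_class", "score"):
                fields.append(_dbf.DbfField(short, "N", 10))
            else:
                fields.append(_dbf.DbfField(short, "N", 19, 6))
        dbf_rows = [{name_map[c]: r[c] for c in _TABLE_COLUMNS} for r in rows]
        path = os.path.join(out_dir, "results.dbf")
        _dbf.write_dbf(path, fields, dbf_rows)
        manifest.append(path)

    if "summary" in formats:
        path = os.path.join(out_dir, "summary.txt")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(format_summary(records, cfg, warnings, name_map))
        manifest.append(path)
    return manifest


def format_summary(
    records: list[AssessmentRecord],
    cfg: AssessmentConfig | None,
    warnings: list[str] | None,
    dbf_name_map: dict[str, str] | None = None,
) -> str:
    """Render the ASCII run summary."""
    lines = ["National responsibility assessment — summary", "=" * 46, ""]
    if cfg is not None:
        lines.append(f"Approach: {cfg.approach.menu_label} ({cfg.approach.name})")
        lines.append(
            f"Pattern thresholds: count local<= {cfg.pc_local_max}, "
            f"regional<= {cfg.pc_regional_max}; area regional fraction "
            f">= {cfg.pa_regional_fraction:.6f}"
        )
        lines.append(
            "Comparison: DP_obs "
            + ("> DP_exp (strict)" if cfg.strict_comparison else ">= DP_exp (non-strict)")
        )
        lines.append(f"Area mode: {cfg.area_mode.value}; sliver tolerance: {cfg.sliver_tolerance:g}")
        lines.append("Responsibility mapping (pattern, DP_obs higher -> class):")
        for (pat, hi), nr in sorted(
            cfg.nr_mapping.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        ):
            lines.append(f"  {pat.value:>8}, {'higher' if hi else 'not higher':>10} -> {nr.label}")
    lines.append("")
    if dbf_name_map:
        lines.append("dBase field-name mapping (10-character limit):")
        for long, short in dbf_name_map.items():
            if long.upper() != short:
                lines.append(f"  {long} -> {short}")
        lines.append("")
    if warnings:
        lines.append("Warnings:")
        lines.extend(f"  - {w}" for w in warnings)
        lines.append("")
    lines.append("Per-species, per-focal-area classes:")
    for r in records:
        pr = (
            f"CP class {r.priority.cp_class} (score {r.priority.score})"
            if r.priority.evaluable
            else "priority not evaluable"
        )
        pat = r.pattern.value if r.pattern else "n/a"
        lines.append(
            f"  {r.species_id} in {r.focal_id}: pattern {pat}, "
            f"DP_exp {r.dp_exp:.6f}, DP_obs {r.dp_obs:.6f}, "
            f"responsibility {r.nr.label}, {pr}"
        )
    lines.append("")
    return "\n".join(lines)
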