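import json
import math
import struct

import pytest
from shapely.geometry import box, Polygon

from nrassess import (
    AssessmentConfig,
    ContainmentPolicy,
    Feature,
    LayerRole,
    LayerSet,
    PLANAR_KM,
    PolygonLayer,
    WGS84,
    check_layerset,
    dissolve_by_attribute,
    polygon_area,
    read_layer,
    spherical_rect_area_km2,
    write_layer,
)
from nrassess.core_model import AreaMode
from nrassess import _dbf
from nrassess.geo_io import infer_role, parse_crs


# --- naming convention and reading ----------------------------------------


@pytest.mark.parametrize(
    "name,role",
    [
        ("s-vulpes_vulpes.geojson", LayerRole.SPECIES),
        ("f-asian_countries.geojson", LayerRole.FOCAL),
        ("g-biomes.geojson", LayerRole.UNITS),
    ],
)
def test_role_inferred_from_filename_prefix(name, role, tmp_path, layerset):
    path = tmp_path / name
    write_layer(layerset.focal, path)
    assert infer_role(path) is role
    assert read_layer(path).role is role


def test_unprefixed_file_requires_role_override(tmp_path, layerset):
    path = tmp_path / "ranges.geojson"
    write_layer(layerset.species[0], path)
    with pytest.raises(ValueError, match="naming convention"):
        read_layer(path)
    layer = read_layer(path, role_override=LayerRole.SPECIES)
    assert layer.role is LayerRole.SPECIES


def test_shapefile_input_rejected_with_guidance(tmp_path):
    path = tmp_path / "s-fox.shp"
    path.write_bytes(b"\x00" * 10)
    with pytest.raises(ValueError, match="GeoJSON"):
        read_layer(path)


def test_invalid_geometry_repaired_on_read(tmp_path):
    bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])  # self-intersecting
    assert not bowtie.is_valid
    layer = PolygonLayer(LayerRole.SPECIES, [Feature("x", bowtie, {})], PLANAR_KM)
    path = tmp_path / "s-bowtie.geojson"
    write_layer(layer, path)
    back = read_layer(path)
    assert back.repairs == 1
    assert back.features[0].geometry.is_valid
    assert polygon_area(back.features[0].geometry, PLANAR_KM, AreaMode.PLANAR) == pytest.approx(2.0)


def test_round_trip_preserves_ids_and_areas(tmp_path, layerset):
    path = tmp_path / "f-countries.geojson"
    write_layer(layerset.focal, path)
    back = read_layer(path)
    assert back.feature_ids() == layerset.focal.feature_ids()
    for orig, rt in zip(layerset.focal.features, back.features):
        a0 = polygon_area(orig.geometry, PLANAR_KM)
        a1 = polygon_area(rt.geometry, back.crs)
        assert math.isclose(a0, a1, rel_tol=1e-9)
    assert back.crs == PLANAR_KM


def test_unknown_crs_rejected():
    with pytest.raises(ValueError, match="coordinate reference"):
        parse_crs("EPSG:32633")


# --- areas -----------------------------------------------------------------


def test_empty_geometry_has_zero_area():
    assert polygon_area(Polygon(), PLANAR_KM) == 0.0


def test_planar_rectangle_area():
    assert polygon_area(box(0, 0, 30, 20), PLANAR_KM) == pytest.approx(600.0)


def test_planar_metre_crs_converts_to_km2():
    from nrassess.geo_io import PLANAR_M

    assert polygon_area(box(0, 0, 30000, 20000), PLANAR_M) == pytest.approx(600.0)


def test_missing_crs_in_auto_mode_rejected():
    with pytest.raises(ValueError, match="spatial reference"):
        polygon_area(box(0, 0, 1, 1), None, AreaMode.AUTO)


def test_geodesic_cell_matches_spherical_closed_form():
    """1-degree equatorial cell against R^2 * dlon * (sin lat2 - sin lat1)."""
    cell = box(0.0, 0.0, 1.0, 1.0)
    got = polygon_area(cell, WGS84, AreaMode.GEODESIC)
    oracle = spherical_rect_area_km2(0.0, 1.0, 0.0, 1.0)
    assert math.isclose(got, oracle, rel_tol=5e-3)
    # for lon/lat-aligned rectangles the line integral is exact
    assert math.isclose(got, oracle, rel_tol=1e-12)


def test_geodesic_area_with_hole():
    outer = box(0.0, 0.0, 2.0, 2.0)
    hole = box(0.5, 0.5, 1.5, 1.5)
    got = polygon_area(outer.difference(hole), WGS84, AreaMode.GEODESIC)
    oracle = spherical_rect_area_km2(0, 2, 0, 2) - spherical_rect_area_km2(0.5, 1.5, 0.5, 1.5)
    assert math.isclose(got, oracle, rel_tol=1e-9)


@pytest.mark.parametrize("split", [0.1, 0.5, 0.83])
@pytest.mark.parametrize("mode,crs", [(AreaMode.PLANAR, PLANAR_KM), (AreaMode.GEODESIC, WGS84)])
def test_area_additivity_under_splitting(split, mode, crs):
    whole = box(0, 0, 8, 5)
    left = box(0, 0, 8 * split, 5)
    right = box(8 * split, 0, 8, 5)
    total = polygon_area(whole, crs, mode)
    parts = polygon_area(left, crs, mode) + polygon_area(right, crs, mode)
    assert math.isclose(total, parts, rel_tol=1e-6)


# --- dissolve --------------------------------------------------------------


def test_dissolve_groups_by_attribute(layerset):
    dissolved = dissolve_by_attribute(layerset.units, "realm")
    assert sorted(dissolved.feature_ids()) == ["R1", "R2"]
    total_before = sum(polygon_area(f.geometry, PLANAR_KM) for f in layerset.units.features)
    total_after = sum(polygon_area(f.geometry, PLANAR_KM) for f in dissolved.features)
    assert math.isclose(total_before, total_after, rel_tol=1e-9)


def test_dissolve_single_value_unions_everything(layerset):
    units = PolygonLayer(
        LayerRole.UNITS,
        [Feature(f.feature_id, f.geometry, {"all": "one"}) for f in layerset.units.features],
        PLANAR_KM,
    )
    dissolved = dissolve_by_attribute(units, "all")
    assert len(dissolved.features) == 1
    total = sum(polygon_area(f.geometry, PLANAR_KM) for f in units.features)
    assert math.isclose(polygon_area(dissolved.features[0].geometry, PLANAR_KM), total, rel_tol=1e-9)


def test_dissolve_missing_field_rejected(layerset):
    with pytest.raises(ValueError, match="lacks attribute"):
        dissolve_by_attribute(layerset.units, "no_such_field")


# --- layer-set validation --------------------------------------------------


def _species_layer(geom, sid="sp"):
    return PolygonLayer(LayerRole.SPECIES, [Feature(sid, geom, {})], PLANAR_KM)


def test_fully_contained_species_has_ratio_one(layerset, cfg):
    report = check_layerset(layerset, cfg)
    assert report.warnings == []
    assert all(report.focal_contained.values())
    assert all(r == pytest.approx(1.0) for r in report.containment_ratio.values())


def test_half_outside_species_clipped_with_warning(layerset, cfg):
    half_out = _species_layer(box(-20, 0, 20, 10), "straddler")
    ls = LayerSet([half_out], layerset.units, layerset.focal, layerset.reference)
    report = check_layerset(ls, cfg)
    assert report.containment_ratio["straddler"] == pytest.approx(0.5)
    assert any("clipped" in w for w in report.warnings)
    clipped = report.layerset.species[0]
    assert polygon_area(clipped.union(), PLANAR_KM) == pytest.approx(200.0)


def test_error_policy_rejects_uncontained_species(layerset, cfg):
    half_out = _species_layer(box(-20, 0, 20, 10))
    ls = LayerSet([half_out], layerset.units, layerset.focal, layerset.reference)
    strict = cfg.replace(containment_policy=ContainmentPolicy.ERROR)
    with pytest.raises(ValueError, match="beyond the reference"):
        check_layerset(ls, strict)


def test_focal_straddling_reference_is_reported(layerset, cfg):
    focal = PolygonLayer(
        LayerRole.FOCAL,
        [Feature("F_out", box(50, -30, 100, 50), {})],
        PLANAR_KM,
    )
    ls = LayerSet(layerset.species, layerset.units, focal, layerset.reference)
    report = check_layerset(ls, cfg)
    assert report.focal_contained["F_out"] is False
    assert not report.ok


def test_crs_mismatch_across_layers_rejected(layerset, cfg):
    wgs_species = PolygonLayer(
        LayerRole.SPECIES, [Feature("sp", box(0, 0, 1, 1), {})], WGS84
    )
    ls = LayerSet([wgs_species], layerset.units, layerset.focal, layerset.reference)
    with pytest.raises(ValueError, match="projection system"):
        check_layerset(ls, cfg)


# --- dBase writer ----------------------------------------------------------


def test_dbf_field_name_truncation_is_deterministic_and_unique():
    names = ["area_dist_in_reference", "area_dist_in_focal", "dp_exp", "species_id"]
    mapping = _dbf.truncate_field_names(names)
    assert mapping == _dbf.truncate_field_names(names)
    assert len(set(mapping.values())) == len(names)
    assert all(len(v) <= 10 for v in mapping.values())
    assert mapping["area_dist_in_reference"] != mapping["area_dist_in_focal"]


def test_dbf_file_structure(tmp_path):
    fields = [
        _dbf.DbfField("SPECIES", "C", 12),
        _dbf.DbfField("SCORE", "N", 10),
        _dbf.DbfField("DP_EXP", "N", 19, 6),
    ]
    rows = [
        {"SPECIES": "endemic", "SCORE": 20, "DP_EXP": 0.0125},
        {"SPECIES": "widespread", "SCORE": 2, "DP_EXP": 0.9},
    ]
    path = tmp_path / "results.dbf"
    _dbf.write_dbf(path, fields, rows)
    raw = path.read_bytes()
    version, _, _, _, n_records, header_size, record_size = struct.unpack(
        "<BBBBIHH", raw[:12]
    )
    assert version == 0x03
    assert n_records == 2
    assert record_size == 1 + 12 + 10 + 19
    assert header_size == 32 + 32 * 3 + 1
    first = raw[header_size : header_size + record_size]
    assert first[1:13].decode().strip() == "endemic"
    assert int(first[13:23]) == 20


def test_outputs_manifest_and_summary(tmp_path, run_count, layerset, cfg):
    from nrassess import write_outputs

    manifest = write_outputs(
        run_count.records, layerset.focal, tmp_path, cfg=run_count.config,
        warnings=run_count.warnings,
    )
    names = {p.split("/")[-1] for p in manifest}
    assert {"results.csv", "results.dbf", "summary.txt"} <= names
    assert sum(n.startswith("map_") and n.endswith(".geojson") for n in names) == 4
    summary = (tmp_path / "summary.txt").read_text()
    assert "by Biome count" in summary
    assert "AREA_DIST_" in summary  # the truncation table is reported
    map_doc = json.loads((tmp_path / "map_endemic.geojson").read_text())
    props = {f["id"]: f["properties"] for f in map_doc["features"]}
    assert props["C1"]["nr"] == "Very high"
    assert props["C2"]["nr"] == "None"
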