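import math

import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from nrassess import (
    AssessmentConfig,
    Feature,
    LayerRole,
    PLANAR_KM,
    PolygonLayer,
    dp_expected,
    dp_observed,
    intersection_area,
    polygon_area,
    raster_oracle_area,
)


def _layer(geoms, role=LayerRole.SPECIES):
    feats = [Feature(str(i), g, {}) for i, g in enumerate(geoms)]
    return PolygonLayer(role, feats, PLANAR_KM)


def test_disjoint_rectangles_have_zero_intersection(cfg):
    res = intersection_area(box(0, 0, 10, 10), box(20, 20, 30, 30), PLANAR_KM)
    assert res.area_intersection == 0.0


def test_contained_geometry_has_full_proportion(cfg):
    res = intersection_area(box(2, 2, 8, 8), box(0, 0, 10, 10), PLANAR_KM)
    assert res.area_intersection == pytest.approx(36.0)
    assert res.proportion_of_first == pytest.approx(1.0)
    assert res.proportion_of_second == pytest.approx(0.36)


def test_strip_overlap_matches_raster_oracle(cfg):
    """30x20 rectangle overlapping a 50x50 square in a 10x20 strip: 200 km²."""
    a = box(40, 0, 70, 20)  # 30 x 20
    b = box(0, 0, 50, 50)  # 50 x 50; overlap strip 40..50 x 0..20
    res = intersection_area(a, b, PLANAR_KM)
    assert res.area_intersection == pytest.approx(200.0)
    oracle = raster_oracle_area(a.intersection(b), cell_km=0.1)
    assert math.isclose(res.area_intersection, oracle, rel_tol=5e-3)


@pytest.mark.parametrize(
    "species,expected",
    [
        (box(0, 0, 100, 100), 1.0),  # covers the whole reference
        (box(200, 200, 210, 210), 0.0),  # disjoint
        (box(10, 10, 40, 30), 0.06),  # 30x20 in 100x100
    ],
)
def test_dp_expected_rectangle_arithmetic(species, expected, cfg):
    reference = _layer([box(0, 0, 100, 100)], LayerRole.REFERENCE)
    assert dp_expected(_layer([species]), reference, cfg) == pytest.approx(expected)


@pytest.mark.parametrize(
    "species,expected",
    [
        (box(100, 100, 110, 110), 0.0),  # absent
        (box(-10, -10, 60, 60), 1.0),  # focal inside the range
        (box(40, 0, 70, 20), 0.08),  # 10x20 overlap on 50x50
    ],
)
def test_dp_observed_rectangle_arithmetic(species, expected, cfg):
    focal = box(0, 0, 50, 50)
    got = dp_observed(_layer([species]), focal, cfg, crs=PLANAR_KM)
    assert got == pytest.approx(expected)


def test_zero_area_inputs_rejected(cfg):
    empty = _layer([box(0, 0, 0, 0)], LayerRole.REFERENCE)
    with pytest.raises(ValueError):
        dp_expected(_layer([box(0, 0, 1, 1)]), empty, cfg)
    with pytest.raises(ValueError):
        dp_observed(_layer([box(0, 0, 1, 1)]), box(5, 5, 5, 5), cfg, crs=PLANAR_KM)


def test_tiling_conservation(world, layerset, cfg):
    """Countries tile the reference, so the area-weighted DP_obs sum equals
    DP_exp times the reference area for every archetype."""
    ref_area = polygon_area(layerset.reference.union(), PLANAR_KM)
    for sp in layerset.species:
        dp_exp = dp_expected(sp, layerset.reference, cfg)
        weighted = 0.0
        for f in layerset.focal.features:
            a = polygon_area(f.geometry, PLANAR_KM)
            weighted += dp_observed(sp, f.geometry, cfg, crs=PLANAR_KM) * a
        assert math.isclose(weighted, dp_exp * ref_area, rel_tol=1e-6)


def test_subdivision_invariance(cfg):
    """Splitting the range into covering sub-polygons changes nothing."""
    reference = _layer([box(0, 0, 100, 100)], LayerRole.REFERENCE)
    whole = _layer([box(10, 10, 40, 30)])
    halves = _layer([box(10, 10, 25, 30), box(25, 10, 40, 30)])
    assert math.isclose(
        dp_expected(whole, reference, cfg),
        dp_expected(halves, reference, cfg),
        rel_tol=1e-9,
    )
    focal = box(0, 0, 50, 50)
    assert math.isclose(
        dp_observed(whole, focal, cfg, crs=PLANAR_KM),
        dp_observed(halves, focal, cfg, crs=PLANAR_KM),
        rel_tol=1e-9,
    )


def test_enlarging_range_never_decreases_proportions(cfg):
    reference = _layer([box(0, 0, 100, 100)], LayerRole.REFERENCE)
    focal = box(0, 0, 50, 50)
    small = box(10, 10, 30, 30)
    grown = small
    prev_exp = dp_expected(_layer([small]), reference, cfg)
    prev_obs = dp_observed(_layer([small]), focal, cfg, crs=PLANAR_KM)
    for pad in (5, 15, 40):
        grown = box(10 - pad * 0.2, 10 - pad * 0.2, 30 + pad, 30 + pad)
        cur_exp = dp_expected(_layer([grown]), reference, cfg)
        cur_obs = dp_observed(_layer([grown]), focal, cfg, crs=PLANAR_KM)
        assert cur_exp >= prev_exp
        assert cur_obs >= prev_obs
        prev_exp, prev_obs = cur_exp, cur_obs


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x0=st.floats(0, 80, allow_nan=False),
    w=st.floats(1, 20, allow_nan=False),
    y0=st.floats(0, 80, allow_nan=False),
    h=st.floats(1, 20, allow_nan=False),
)
def test_dp_expected_matches_interval_arithmetic(x0, w, y0, h):
    """For any rectangle inside the reference, DP_exp equals the
    closed-form width x height over the reference area."""
    cfg = AssessmentConfig()
    reference = _layer([box(0, 0, 100, 100)], LayerRole.REFERENCE)
    species = _layer([box(x0, y0, x0 + w, y0 + h)])
    assert math.isclose(
        dp_expected(species, reference, cfg), w * h / 10000.0, rel_tol=1e-9
    )


def test_proportions_always_clamped(cfg):
    reference = _layer([box(0, 0, 10, 10)], LayerRole.REFERENCE)
    huge = _layer([box(-100, -100, 100, 100)])
    assert dp_expected(huge, reference, cfg) == 1.0
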