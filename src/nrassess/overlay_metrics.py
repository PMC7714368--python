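"""Intersection areas and the expected / observed distribution proportions.

The expected distribution proportion DP_exp of a species is the share
of the reference area covered by its range,

    DP_exp = area(distribution ∩ reference) / area(reference),

and the observed distribution proportion in a focal area is

    DP_obs = area(distribution ∩ focal) / area(focal).

A focal area holding a larger share of the species' range than its own
share of the reference area (DP_obs > DP_exp) is over-represented and
carries elevated responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

from shapely.geometry.base import BaseGeometry

from .core_model import AreaMode, AssessmentConfig
from .geo_io import CRS, PolygonLayer, polygon_area


def _geom(obj) -> BaseGeometry:
    return obj.union() if isinstance(obj, PolygonLayer) else obj


def _clamp01(x: float) -> float:
    # overlay round-off can push ratios a hair outside [0, 1]
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


@dataclass(frozen=True)
class OverlapResult:
    area_intersection: float  # km²
    proportion_of_first: float
    proportion_of_second: float


def intersection_area(
    a, b, crs: CRS | None, mode: AreaMode = AreaMode.AUTO
) -> OverlapResult:
    """Vector-overlay intersection of two polygon sets, measured in km²."""
    ga, gb = _geom(a), _geom(b)
    inter = polygon_area(ga.intersection(gb), crs, mode)
    area_a = polygon_area(ga, crs, mode)
    area_b = polygon_area(gb, crs, mode)
    inter = min(inter, area_a, area_b)  # numeric guard; set theory requires it
    return OverlapResult(
        area_intersection=inter,
        proportion_of_first=_clamp01(inter / area_a) if area_a > 0 else 0.0,
        proportion_of_second=_clamp01(inter / area_b) if area_b > 0 else 0.0,
    )


def dp_expected(species, reference, cfg: AssessmentConfig) -> float:
    """DP_exp: within-reference range area over reference area, in [0, 1]."""
    ref = _geom(reference)
    crs = reference.crs if isinstance(reference, PolygonLayer) else getattr(species, "crs", None)
    ref_area = polygon_area(ref, crs, cfg.area_mode)
    if ref_area <= 0:
        raise ValueError("reference area must have positive area")
    inter = polygon_area(_geom(species).intersection(ref), crs, cfg.area_mode)
    return _clamp01(inter / ref_area)


def dp_observed(species, focal_feature, cfg: AssessmentConfig, crs: CRS | None = None) -> float:
    """DP_obs: within-focal range area over focal area, in [0, 1]."""
    foc = _geom(focal_feature)
    if crs is None:
        crs = getattr(species, "crs", None)
    focal_area = polygon_area(foc, crs, cfg.area_mode)
    if focal_area <= 0:
        raise ValueError("focal area must have positive area")
    inter = polygon_area(_geom(species).intersection(foc), crs, cfg.area_mode)
    return _clamp01(inter / focal_area)
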