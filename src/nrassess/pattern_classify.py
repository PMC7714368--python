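"""Distribution-pattern classification: local, regional, or wide.

Two interchangeable rules relate a species' within-reference range to
the biogeographical units (environmental zones, ecoregions):

* Polygon Count-Approach (PC-A): the number of units the range
  overlaps. Few units -> local, several -> regional, many -> wide.
* Polygon Area-Approach (PA-A): the share of the range area falling in
  the single best-covered unit. One unit -> local; at least the
  regional fraction (default two-thirds) in one unit -> regional;
  otherwise wide.

Counts can mislead where environmental conditions change rapidly over
space (many small units under a small range), which is what the
area-based alternative addresses; overlaps below the sliver tolerance
are ignored in both rules.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_model import AssessmentConfig, Approach, DistributionPattern
from .geo_io import PolygonLayer, polygon_area


@dataclass(frozen=True)
class UnitOccupancy:
    """Per-biogeographical-unit overlap of a within-reference range."""

    per_unit: dict  # unit_id -> overlap area km² (above sliver tolerance)
    n_units: int
    p_max: float  # largest per-unit share of the within-reference range area

    @property
    def total_area(self) -> float:
        return sum(self.per_unit.values())


def compute_occupancy(
    species,
    units: PolygonLayer,
    reference,
    cfg: AssessmentConfig,
) -> UnitOccupancy:
    """Overlay a species range (already clipped to the reference) on the units.

    Units whose overlap does not exceed ``sliver_tolerance`` times the
    reference area are excluded: a range merely touching a unit along a
    boundary does not occupy it.
    """
    from .overlay_metrics import _geom

    sp = _geom(species)
    ref = _geom(reference)
    crs = units.crs
    mode = cfg.area_mode
    ref_area = polygon_area(ref, crs, mode)
    tol = cfg.sliver_tolerance * ref_area
    total = polygon_area(sp, crs, mode)
    if total <= tol:
        raise ValueError("species has no distribution inside the reference area")
    per_unit: dict[str, float] = {}
    for f in units.features:
        a = polygon_area(sp.intersection(f.geometry), crs, mode)
        if a > tol:
            per_unit[f.feature_id] = a
    if not per_unit:
        raise ValueError("species range overlaps no biogeographical unit")
    p_max = max(per_unit.values()) / total
    return UnitOccupancy(per_unit=per_unit, n_units=len(per_unit), p_max=min(p_max, 1.0))


def classify_pattern_count(occ: UnitOccupancy, cfg: AssessmentConfig) -> DistributionPattern:
    """PC-A: pattern from the count of occupied units."""
    if occ.n_units < 1:
        raise ValueError("cannot classify a species occupying no unit")
    if occ.n_units <= cfg.pc_local_max:
        return DistributionPattern.LOCAL
    if occ.n_units <= cfg.pc_regional_max:
        return DistributionPattern.REGIONAL
    return DistributionPattern.WIDE


def classify_pattern_area(occ: UnitOccupancy, cfg: AssessmentConfig) -> DistributionPattern:
    """PA-A: pattern from the largest per-unit area share.

    A share exactly at the regional fraction counts as regional
    (inclusive bound: two-thirds of the range *is located* in one unit).
    """
    if occ.n_units < 1:
        raise ValueError("cannot classify a species occupying no unit")
    if occ.n_units == 1:
        return DistributionPattern.LOCAL
    if occ.p_max >= cfg.pa_regional_fraction:
        return DistributionPattern.REGIONAL
    return DistributionPattern.WIDE


def classify_pattern(occ: UnitOccupancy, cfg: AssessmentConfig) -> DistributionPattern:
    """Dispatch on the configured approach."""
    if cfg.approach is Approach.PC_A:
        return classify_pattern_count(occ, cfg)
    return classify_pattern_area(occ, cfg)
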