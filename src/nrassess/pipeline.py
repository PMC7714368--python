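"""Run orchestration: assess many species over many focal areas.

The workflow per species: clip the range to the reference area,
classify its distribution pattern against the biogeographical units
(once per species — pattern is a property of the species, not of a
focal area), compute DP_exp, and then per focal area compute DP_obs,
compare, and assign responsibility and priority classes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    AssessmentConfig,
    AssessmentRecord,
    DistributionPattern,
    IUCNCategory,
    PriorityResult,
    ResponsibilityClass,
    validate_config,
)
from .geo_io import LayerSet, PolygonLayer, check_layerset, polygon_area
from .overlay_metrics import _clamp01
from .pattern_classify import classify_pattern, compute_occupancy
from .priority import build_priority_matrix, cp_lookup
from .responsibility import compare_dp, nr_class

logger = logging.getLogger("nrassess")


@dataclass
class AssessmentRun:
    config: AssessmentConfig
    records: list[AssessmentRecord]
    warnings: list[str] = field(default_factory=list)
    manifest: list[str] = field(default_factory=list)
    per_country_counts: dict = field(default_factory=dict)

    def record(self, species_id: str, focal_id: str) -> AssessmentRecord:
        for r in self.records:
            if r.species_id == species_id and r.focal_id == focal_id:
                return r
        raise KeyError((species_id, focal_id))

    @property
    def species_ids(self) -> list[str]:
        seen = dict.fromkeys(r.species_id for r in self.records)
        return list(seen)

    @property
    def focal_ids(self) -> list[str]:
        seen = dict.fromkeys(r.focal_id for r in self.records)
        return list(seen)


def species_id_of(layer: PolygonLayer) -> str:
    """Species identity: the ``s-<name>`` filename stem, else the feature id."""
    base = os.path.basename(str(layer.source_path))
    if base.startswith("s-"):
        return os.path.splitext(base)[0][2:]
    if layer.features:
        return layer.features[0].feature_id
    return base


def assess(
    ls: LayerSet,
    metadata: dict[str, IUCNCategory],
    cfg: AssessmentConfig,
) -> AssessmentRun:
    """Assess every species against every focal area.

    Species named in the metadata without a matching range layer are
    listed as missing; species with a range but no metadata are
    assessed for responsibility with priority marked not evaluable.
    Deterministic given inputs and configuration.
    """
    cfg = validate_config(cfg)
    report = check_layerset(ls, cfg)
    ls = report.layerset
    run = AssessmentRun(config=cfg, records=[], warnings=list(report.warnings))

    layer_ids = {species_id_of(sp) for sp in ls.species}
    for sid in metadata:
        if sid not in layer_ids:
            run.warnings.append(f"species {sid!r} listed in metadata but no s- layer found")
    if not ls.species:
        run.warnings.append("no species layers given: empty run")
        return run

    matrix = build_priority_matrix()
    mode = cfg.area_mode
    crs = ls.reference.crs
    ref_geom = ls.reference.union()
    area_ref = polygon_area(ref_geom, crs, mode)
    tol = cfg.sliver_tolerance * area_ref

    for sp in ls.species:
        sid = species_id_of(sp)
        category = metadata.get(sid)
        if category is None:
            run.warnings.append(
                f"species {sid!r} has no IUCN category: priority not evaluable"
            )
        sp_geom = sp.union().intersection(ref_geom)
        area_in_ref = polygon_area(sp_geom, crs, mode)
        containment = report.containment_ratio.get(sid, 1.0)
        pattern: DistributionPattern | None = None
        n_units, p_max = 0, 0.0
        if area_in_ref > tol:
            occ = compute_occupancy(sp_geom, ls.units, ref_geom, cfg)
            n_units, p_max = occ.n_units, occ.p_max
            pattern = classify_pattern(occ, cfg)
        else:
            run.warnings.append(f"species {sid!r} has no range inside the reference area")
        dp_exp = _clamp01(area_in_ref / area_ref)

        for f in ls.focal.features:
            area_focal = polygon_area(f.geometry, crs, mode)
            area_in_focal = polygon_area(sp_geom.intersection(f.geometry), crs, mode)
            dp_obs = _clamp01(area_in_focal / area_focal) if area_focal > 0 else 0.0
            present = area_in_focal > tol
            higher = compare_dp(dp_obs, dp_exp, cfg)
            nr = nr_class(pattern, higher, present and pattern is not None, cfg)
            priority = (
                cp_lookup(category, nr, matrix)
                if nr is not ResponsibilityClass.NONE
                else PriorityResult(evaluable=False)
            )
            run.records.append(
                AssessmentRecord(
                    species_id=sid,
                    focal_id=f.feature_id,
                    area_reference=area_ref,
                    area_focal=area_focal,
                    area_dist_in_reference=area_in_ref,
                    area_dist_in_focal=area_in_focal,
                    dp_exp=dp_exp,
                    dp_obs=dp_obs,
                    n_units=n_units,
                    p_max=p_max,
                    pattern=pattern,
                    nr=nr,
                    priority=priority,
                    containment_ratio=containment,
                )
            )
    run.per_country_counts = count_by_class(run)
    return run


def count_by_class(run: AssessmentRun, by: str = "nr") -> dict:
    """Per focal area, species counts per responsibility ('nr') or
    priority ('cp') class. NONE / not-evaluable entries are counted
    under their own key so totals remain checkable."""
    counts: dict = {}
    for fid in run.focal_ids:
        counts[fid] = {}
    for r in run.records:
        if by == "nr":
            key = r.nr
        elif by == "cp":
            key = r.priority.cp_class if r.priority.evaluable else None
        else:
            raise ValueError(f"unknown count key: {by!r}")
        counts[r.focal_id][key] = counts[r.focal_id].get(key, 0) + 1
    return counts


@dataclass
class ApproachComparison:
    """Count-approach vs area-approach comparison over one species pool.

    Countries are ranked by descending species count (ties broken by
    focal-area id); quartile thresholds come from the pooled
    distribution of per-country counts of both approaches, with
    inclusive linear interpolation.
    """

    min_class: ResponsibilityClass
    counts_pc: dict
    counts_pa: dict
    per_country_delta: dict
    summary_stats: dict
    quartile_thresholds: tuple
    rank_agreement: dict


def _counts_at_least(run: AssessmentRun, min_class: ResponsibilityClass) -> dict:
    counts = {fid: 0 for fid in run.focal_ids}
    for r in run.records:
        if r.nr >= min_class and r.nr is not ResponsibilityClass.NONE:
            counts[r.focal_id] += 1
    return counts


def _stats(values) -> dict:
    v = np.asarray(sorted(values), dtype=float)
    return {
        "min": float(v.min()),
        "q25": float(np.percentile(v, 25)),
        "median": float(np.percentile(v, 50)),
        "q75": float(np.percentile(v, 75)),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }


def _ranks(counts: dict) -> dict:
    ordered = sorted(counts, key=lambda fid: (-counts[fid], fid))
    return {fid: i + 1 for i, fid in enumerate(ordered)}


def compare_approaches(
    run_count: AssessmentRun,
    run_area: AssessmentRun,
    min_class: ResponsibilityClass = ResponsibilityClass.MEDIUM,
) -> ApproachComparison:
    """Compare per-country species counts at >= ``min_class`` between runs."""
    if set(run_count.species_ids) != set(run_area.species_ids) or set(
        run_count.focal_ids
    ) != set(run_area.focal_ids):
        raise ValueError("runs cover different species or focal-area sets")
    for attr in ("pc_local_max", "pc_regional_max", "pa_regional_fraction",
                 "strict_comparison", "sliver_tolerance"):
        if getattr(run_count.config, attr) != getattr(run_area.config, attr):
            raise ValueError(f"runs differ in non-approach configuration: {attr}")

    counts_pc = _counts_at_least(run_count, min_class)
    counts_pa = _counts_at_least(run_area, min_class)
    delta = {fid: counts_pa[fid] - counts_pc[fid] for fid in counts_pc}
    pooled = np.asarray(list(counts_pc.values()) + list(counts_pa.values()), dtype=float)
    thresholds = tuple(float(np.percentile(pooled, q)) for q in (25, 50, 75))

    ranks_pc, ranks_pa = _ranks(counts_pc), _ranks(counts_pa)
    ranges = ["0-25%", "25-50%", "50-75%", "75-100%"]
    agreement = {rng: {"true": 0, "false": 0} for rng in ranges}
    q1, q2, q3 = thresholds
    for fid, c in counts_pc.items():
        if c <= q1:
            rng = "0-25%"
        elif c <= q2:
            rng = "25-50%"
        elif c <= q3:
            rng = "50-75%"
        else:
            rng = "75-100%"
        agreement[rng]["true" if ranks_pc[fid] == ranks_pa[fid] else "false"] += 1

    return ApproachComparison(
        min_class=min_class,
        counts_pc=counts_pc,
        counts_pa=counts_pa,
        per_country_delta=delta,
        summary_stats={
            "PC-A": _stats(counts_pc.values()),
            "PA-A": _stats(counts_pa.values()),
            "PA-A minus PC-A": _stats(delta.values()),
        },
        quartile_thresholds=thresholds,
        rank_agreement=agreement,
    )
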