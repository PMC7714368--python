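"""Domain types shared by every stage of a responsibility assessment.

The assessment crosses three ingredients for each (species, focal area)
pair: the species' distribution pattern within the reference area
(local / regional / wide), the comparison of its observed distribution
proportion in the focal area against the proportion expected from the
focal area's size, and the species' global IUCN Red List category.
These types carry that state between modules and pin down the
configurable thresholds.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Optional


class IUCNCategory(enum.Enum):
    """Global IUCN Red List categories accepted by the assessment.

    ``DD`` (Data Deficient) and ``NE`` (Not Evaluated) species can be
    assessed for national responsibility but carry no conservation
    priority score; they are flagged *not evaluable*.
    """

    EW = "Extinct in the Wild"
    CR = "Critically Endangered"
    EN = "Endangered"
    VU = "Vulnerable"
    NT = "Near Threatened"
    LC = "Least Concern"
    DD = "Data Deficient"
    NE = "Not Evaluated"

    @property
    def evaluable(self) -> bool:
        return self not in (IUCNCategory.DD, IUCNCategory.NE)

    # threat severity, for ordering checks (LC least, EW most severe)
    @property
    def severity(self) -> int:
        order = ["LC", "NT", "VU", "EN", "CR", "EW"]
        return order.index(self.name) if self.name in order else -1


_IUCN_BY_NAME = {c.value.lower(): c for c in IUCNCategory}
_IUCN_BY_CODE = {c.name.lower(): c for c in IUCNCategory}


def parse_iucn_category(text: str) -> IUCNCategory:
    """Parse a two-letter code or full category name, case-insensitively.

    >>> parse_iucn_category("Endangered").name
    'EN'
    >>> parse_iucn_category("lc").name
    'LC'
    """
    if not text or not text.strip():
        raise ValueError("empty IUCN category")
    key = " ".join(text.strip().lower().split())
    cat = _IUCN_BY_CODE.get(key) or _IUCN_BY_NAME.get(key)
    if cat is None:
        raise ValueError(f"unrecognized IUCN category: {text!r}")
    return cat


class DistributionPattern(enum.Enum):
    """Ternary classification of a species' within-reference range."""

    LOCAL = "local"
    REGIONAL = "regional"
    WIDE = "wide"


class ResponsibilityClass(enum.IntEnum):
    """National-responsibility levels; NONE means absent from the focal area."""

    NONE = 0
    BASIC = 1
    MEDIUM = 2
    HIGH = 3
    VERY_HIGH = 4

    @property
    def label(self) -> str:
        return {
            ResponsibilityClass.NONE: "None",
            ResponsibilityClass.BASIC: "Basic",
            ResponsibilityClass.MEDIUM: "Medium",
            ResponsibilityClass.HIGH: "High",
            ResponsibilityClass.VERY_HIGH: "Very high",
        }[self]


class Approach(enum.Enum):
    """Pattern-classification approach.

    PC_A — Polygon Count-Approach: pattern from the number of occupied
    biogeographical units. PA_A — Polygon Area-Approach: pattern from
    the per-unit share of the within-reference range area.
    """

    PC_A = "count"
    PA_A = "area"

    @property
    def menu_label(self) -> str:
        # labels match the tool's menu wording for the two options
        return "by Biome count" if self is Approach.PC_A else "by biome-area"


class AreaMode(enum.Enum):
    GEODESIC = "geodesic"
    PLANAR = "planar"
    AUTO = "auto"


class ContainmentPolicy(enum.Enum):
    WARN_AND_CLIP = "warn_and_clip"
    ERROR = "error"


@dataclass(frozen=True)
class PriorityResult:
    """Conservation-priority class (1-4) and score, or not evaluable."""

    evaluable: bool
    cp_class: Optional[int] = None
    score: Optional[int] = None

    def __post_init__(self):
        if self.evaluable:
            if self.cp_class not in (1, 2, 3, 4) or self.score is None:
                raise ValueError("evaluable result requires cp_class in 1..4 and a score")
        elif self.cp_class is not None or self.score is not None:
            raise ValueError("not-evaluable result must not carry class or score")


# default responsibility mapping: pattern x (observed proportion higher
# than expected?) -> class.  Monotone: for a fixed pattern, "higher"
# never lowers the class; for a fixed comparison, narrower patterns
# never lower it.
DEFAULT_NR_MAPPING: dict[tuple[DistributionPattern, bool], ResponsibilityClass] = {
    (DistributionPattern.WIDE, False): ResponsibilityClass.BASIC,
    (DistributionPattern.WIDE, True): ResponsibilityClass.MEDIUM,
    (DistributionPattern.REGIONAL, False): ResponsibilityClass.MEDIUM,
    (DistributionPattern.REGIONAL, True): ResponsibilityClass.HIGH,
    (DistributionPattern.LOCAL, False): ResponsibilityClass.HIGH,
    (DistributionPattern.LOCAL, True): ResponsibilityClass.VERY_HIGH,
}


@dataclass
class AssessmentConfig:
    """Thresholds and switches governing one assessment run.

    Parameters
    ----------
    approach
        PC_A (unit counts) or PA_A (unit area shares).
    pc_local_max
        PC-A: at most this many occupied units -> local (default 1).
    pc_regional_max
        PC-A: up to this many units -> regional; beyond -> wide (default 3).
    pa_regional_fraction
        PA-A: smallest share of the within-reference range in a single
        unit that still counts as regional (default 2/3, inclusive).
    strict_comparison
        If true (default), the observed proportion must strictly exceed
        the expected one; ties resolve to the lower-responsibility branch.
    area_mode
        AUTO picks geodesic area for geographic coordinate systems and
        planar area for projected ones.
    sliver_tolerance
        Overlaps below this fraction of the reference area are treated
        as absence (boundary slivers).
    nr_mapping
        Override for the pattern x comparison -> class table; must be
        monotone in both arguments.
    """

    approach: Approach = Approach.PC_A
    pc_local_max: int = 1
    pc_regional_max: int = 3
    pa_regional_fraction: float = 2.0 / 3.0
    strict_comparison: bool = True
    area_mode: AreaMode = AreaMode.AUTO
    containment_policy: ContainmentPolicy = ContainmentPolicy.WARN_AND_CLIP
    sliver_tolerance: float = 1e-9
    nr_mapping: dict = field(default_factory=lambda: dict(DEFAULT_NR_MAPPING))

    def replace(self, **kw) -> "AssessmentConfig":
        d = {**self.__dict__, **kw}
        return validate_config(AssessmentConfig(**d))


def _check_mapping_monotone(mapping) -> None:
    pats = [DistributionPattern.WIDE, DistributionPattern.REGIONAL, DistributionPattern.LOCAL]
    if set(mapping) != {(p, h) for p in pats for h in (False, True)}:
        raise ValueError("responsibility mapping must have exactly 6 (pattern, higher) entries")
    for p in pats:
        if mapping[(p, True)] < mapping[(p, False)]:
            raise ValueError(f"mapping not monotone in comparison outcome at {p}")
    for h in (False, True):
        for narrower, wider in ((pats[1], pats[0]), (pats[2], pats[1])):
            if mapping[(narrower, h)] < mapping[(wider, h)]:
                raise ValueError(f"mapping not monotone in pattern at higher={h}")
    if ResponsibilityClass.NONE in mapping.values():
        raise ValueError("NONE is reserved for absent species and cannot be mapped")


def validate_config(cfg: AssessmentConfig) -> AssessmentConfig:
    """Validate threshold invariants; returns the config unchanged if valid."""
    if not (0.0 < cfg.pa_regional_fraction <= 1.0):
        raise ValueError(
            f"pa_regional_fraction must lie in (0, 1], got {cfg.pa_regional_fraction}"
        )
    if cfg.pc_local_max < 1:
        raise ValueError(f"pc_local_max must be >= 1, got {cfg.pc_local_max}")
    if cfg.pc_regional_max < cfg.pc_local_max:
        raise ValueError(
            f"pc_regional_max ({cfg.pc_regional_max}) must be >= pc_local_max ({cfg.pc_local_max})"
        )
    if not (0.0 <= cfg.sliver_tolerance < 1.0):
        raise ValueError("sliver_tolerance must be a small fraction in [0, 1)")
    _check_mapping_monotone(cfg.nr_mapping)
    return cfg


@dataclass
class AssessmentRecord:
    """One row of the result table: a (species, focal area) pair.

    Areas are km²; ``dp_exp`` and ``dp_obs`` are the expected and observed
    distribution proportions — (range ∩ reference)/reference and
    (range ∩ focal)/focal respectively.  ``containment_ratio`` is the
    fraction of the species' total range that lies inside the reference
    area (1.0 when fully contained).
    """

    species_id: str
    focal_id: str
    area_reference: float
    area_focal: float
    area_dist_in_reference: float
    area_dist_in_focal: float
    dp_exp: float
    dp_obs: float
    n_units: int
    p_max: float
    pattern: DistributionPattern
    nr: ResponsibilityClass
    priority: PriorityResult
    containment_ratio: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pattern"] = self.pattern.value
        d["nr"] = self.nr.name
        d["priority"] = {
            "evaluable": self.priority.evaluable,
            "cp_class": self.priority.cp_class,
            "score": self.priority.score,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AssessmentRecord":
        d = dict(d)
        d["pattern"] = DistributionPattern(d["pattern"])
        d["nr"] = ResponsibilityClass[d["nr"]]
        p = d["priority"]
        d["priority"] = PriorityResult(
            evaluable=p["evaluable"], cp_class=p["cp_class"], score=p["score"]
        )
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "AssessmentRecord":
        return cls.from_dict(json.loads(s))


def read_species_metadata(path) -> dict[str, IUCNCategory]:
    """Read a species metadata table mapping species_id -> IUCN category.

    Accepts CSV or whitespace-delimited text with two columns
    (``species_id``, ``iucn_category``); a header row is optional.
    """
    out: dict[str, IUCNCategory] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "," in line:
                parts = [p.strip() for p in line.split(",")]
            else:
                cols = line.split()
                parts = [cols[0], " ".join(cols[1:])] if len(cols) > 1 else cols
            if len(parts) < 2 or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected species_id and category")
            sid, cat = parts[0], parts[1]
            if lineno == 1 and sid.lower() in ("species_id", "species", "id"):
                continue
            out[sid] = parse_iucn_category(cat)
    return out


def read_species_list(path) -> list[str]:
    """Read an ASCII species-list file: names separated by semicolons."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    return [name.strip() for name in text.split(";") if name.strip()]
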