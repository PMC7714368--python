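"""Conservation-priority classes and scores.

National responsibility is crossed with the species' global IUCN Red
List category to give a priority class (1 = highest priority, 4 =
lowest) and an integer point score. The 6 x 4 matrix is irregular
expert-assigned data, so it is shipped as a literal table guarded by a
checksum — it is never computed from a formula. Data Deficient and Not
Evaluated species, and species a country holds no responsibility for,
receive no priority ("not evaluable").
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass

from .core_model import IUCNCategory, PriorityResult, ResponsibilityClass

# rows: threat category; columns: Very high, High, Medium, Basic
# each cell: (priority class, score)
_PRIORITY_TABLE: dict[str, tuple[tuple[int, int], ...]] = {
    "EW": ((1, 25), (1, 20), (2, 17), (2, 16)),
    "CR": ((1, 22), (2, 17), (2, 14), (2, 13)),
    "EN": ((1, 20), (2, 15), (3, 12), (3, 11)),
    "VU": ((2, 18), (2, 13), (3, 10), (4, 9)),
    "NT": ((2, 16), (3, 11), (4, 8), (4, 7)),
    "LC": ((3, 11), (4, 6), (4, 3), (4, 2)),
}

_COLUMNS = (
    ResponsibilityClass.VERY_HIGH,
    ResponsibilityClass.HIGH,
    ResponsibilityClass.MEDIUM,
    ResponsibilityClass.BASIC,
)

# sha256 of the canonical serialization; guards against accidental edits
_TABLE_SHA256 = "b1f63207cc742e8413ae13448dcd47e332e16c945170f950b17adb9bfff6a3d7"


def _table_digest() -> str:
    canon = ";".join(
        f"{cat}:" + ",".join(f"{c}({s})" for c, s in _PRIORITY_TABLE[cat])
        for cat in ("EW", "CR", "EN", "VU", "NT", "LC")
    )
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass(frozen=True)
class PriorityMatrix:
    """(IUCN category, responsibility class) -> (priority class, score)."""

    entries: dict

    def entry(self, category: IUCNCategory, nr: ResponsibilityClass) -> tuple[int, int]:
        return self.entries[(category, nr)]


def build_priority_matrix() -> PriorityMatrix:
    """The 24-entry priority matrix (6 evaluable categories x 4 classes)."""
    if _table_digest() != _TABLE_SHA256:
        raise RuntimeError("priority table corrupted: checksum mismatch")
    entries = {}
    for cat_code, cells in _PRIORITY_TABLE.items():
        cat = IUCNCategory[cat_code]
        for nr, (cp, score) in zip(_COLUMNS, cells):
            entries[(cat, nr)] = (cp, score)
    return PriorityMatrix(entries=entries)


def cp_lookup(
    category: IUCNCategory | None,
    nr: ResponsibilityClass,
    matrix: PriorityMatrix | None = None,
) -> PriorityResult:
    """Priority for one (category, responsibility) pair.

    Not evaluable when the category is DD/NE or missing, or when the
    country holds no responsibility for the species.
    """
    if category is None or not category.evaluable or nr is ResponsibilityClass.NONE:
        return PriorityResult(evaluable=False)
    matrix = matrix or build_priority_matrix()
    cp, score = matrix.entry(category, nr)
    return PriorityResult(evaluable=True, cp_class=cp, score=score)


def matrix_to_csv(matrix: PriorityMatrix | None = None) -> str:
    """CSV export of the matrix, for report appendices."""
    matrix = matrix or build_priority_matrix()
    buf = io.StringIO()
    buf.write("iucn_category," + ",".join(c.label for c in _COLUMNS) + "\n")
    for cat_code in ("EW", "CR", "EN", "VU", "NT", "LC"):
        cat = IUCNCategory[cat_code]
        cells = [matrix.entry(cat, nr) for nr in _COLUMNS]
        buf.write(cat.value + "," + ",".join(f"Class {c} ({s})" for c, s in cells) + "\n")
    return buf.getvalue()
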