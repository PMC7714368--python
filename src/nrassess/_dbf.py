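"""Minimal dBase III (.dbf) table writer.

Only what the attribute-table export needs: character and numeric
fields, ASCII data, fixed-width records. Field names are at most 10
characters (a dBase format limit); callers are expected to truncate
and deduplicate names before handing them in.
"""

from __future__ import annotations

import datetime
import struct
from dataclasses import dataclass


@dataclass(frozen=True)
class DbfField:
    name: str  # <= 10 chars, ASCII
    ftype: str  # 'C' (character) or 'N' (numeric)
    length: int
    decimals: int = 0

    def __post_init__(self):
        if len(self.name) > 10 or not self.name.isascii():
            raise ValueError(f"dBase field name too long or non-ASCII: {self.name!r}")
        if self.ftype not in ("C", "N"):
            raise ValueError(f"unsupported dBase field type: {self.ftype!r}")
        if not (1 <= self.length <= 254):
            raise ValueError(f"dBase field length out of range: {self.length}")


def _format_value(value, field: DbfField) -> bytes:
    if field.ftype == "C":
        s = "" if value is None else str(value)
        return s.encode("ascii", "replace")[: field.length].ljust(field.length)
    if value is None or value == "":
        return b" " * field.length
    s = f"{float(value):.{field.decimals}f}" if field.decimals else str(int(value))
    if len(s) > field.length:
        raise ValueError(f"value {s} does not fit dBase field {field.name}")
    return s.encode("ascii").rjust(field.length)


def write_dbf(path, fields: list[DbfField], rows: list[dict], *, today=None) -> None:
    """Write ``rows`` (dicts keyed by field name) as a dBase III table."""
    today = today or datetime.date.today()
    record_size = 1 + sum(f.length for f in fields)  # leading deletion flag
    header_size = 32 + 32 * len(fields) + 1
    with open(path, "wb") as fh:
        fh.write(
            struct.pack(
                "<BBBBIHH20x",
                0x03,
                today.year % 100,
                today.month,
                today.day,
                len(rows),
                header_size,
                record_size,
            )
        )
        for f in fields:
            fh.write(
                struct.pack(
                    "<11sc4xBB14x",
                    f.name.encode("ascii"),
                    f.ftype.encode("ascii"),
                    f.length,
                    f.decimals,
                )
            )
        fh.write(b"\x0d")
        for row in rows:
            fh.write(b" ")
            for f in fields:
                fh.write(_format_value(row.get(f.name), f))
        fh.write(b"\x1a")


def truncate_field_names(names: list[str]) -> dict[str, str]:
    """Deterministically map arbitrary column names to unique dBase names.

    Uppercase, truncated to 10 characters; collisions get a numeric
    suffix in input order.
    """
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        base = name.upper()[:10]
        candidate, k = base, 1
        while candidate in used:
            k += 1
            suffix = f"_{k}"
            candidate = base[: 10 - len(suffix)] + suffix
        mapping[name] = candidate
        used.add(candidate)
    return mapping
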