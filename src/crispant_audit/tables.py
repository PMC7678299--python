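"""Deterministic TSV report writing."""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence


@dataclass(frozen=True)
class TableSchema:
    """Fixed column order plus the sort key that makes output canonical."""

    columns: tuple[str, ...]
    key: tuple[str, ...] = ()


def _format(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_table(
    records: Sequence[Mapping[str, object]],
    schema: TableSchema,
    path: str | Path,
) -> None:
    """Write records as a sorted, tab-separated, UTF-8 table.

    Column order and row order (by ``schema.key``) are fixed so identical
    record sets produce byte-identical files; floats use 6 significant
    digits; None/NaN become NA.
    """
    for rec in records:
        missing = set(schema.columns) - set(rec)
        if missing:
            raise ValueError(f"record missing field(s): {', '.join(sorted(missing))}")
    rows = sorted(records, key=lambda r: tuple(str(r[k]) for k in schema.key))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(schema.columns) + "\n")
        for rec in rows:
            fh.write("\t".join(_format(rec[c]) for c in schema.columns) + "\n")
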