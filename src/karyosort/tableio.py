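"""Reading and writing the cytogenetic count-table TSV dialect.

One header row; columns ``sample_id``, ``line``, ``mi_counts`` (tokens in
the count notation, ``;``-separated), ``m_count`` (one token or empty), and
optionally ``printed_x``/``printed_y`` for tables transcribed from print.
Missing cells may be empty, ``-`` or the typographic ``–``.  Tab-separated,
UTF-8, Unix newlines.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from .counts import CountNotation, CountParseError, ObservedCountRecord, parse_count_notation

__all__ = ["TableFormatError", "read_count_table", "write_count_table"]

REQUIRED_COLUMNS = ("sample_id", "line", "mi_counts", "m_count")
OPTIONAL_COLUMNS = ("printed_x", "printed_y")
_MISSING = {"", "-", "–"}

_LINE_ALIASES = {
    "spain": "Spain",
    "sweden": "Sweden",
    "f1": "F1",
    "f2": "F2",
    "f3": "F3",
    "f4": "F4",
    "f_1_ hybrid": "F1",
    "f_2_ hybrid": "F2",
    "f_3_ hybrid": "F3",
    "f_4_ hybrid": "F4",
    "f1 hybrid": "F1",
    "f2 hybrid": "F2",
    "f3 hybrid": "F3",
    "f4 hybrid": "F4",
}


class TableFormatError(ValueError):
    """Malformed count table; the message carries the offending line number."""


def _normalize_line(label: str, lineno: int) -> str:
    key = label.strip().lower()
    if key not in _LINE_ALIASES:
        raise TableFormatError(f"line {lineno}: unknown line label {label!r}")
    return _LINE_ALIASES[key]


def read_count_table(source: Union[str, Path, TextIO]) -> list[ObservedCountRecord]:
    """Parse a count-table TSV into observation records.

    Raises :class:`TableFormatError` with a line number for a missing
    column, an unparseable token or a record with no observation at all.
    An input holding only the header yields an empty list.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise TableFormatError("line 1: empty file")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise TableFormatError(f"line 1: missing required column(s) {missing}")
    col = {name: header.index(name) for name in header}

    records: list[ObservedCountRecord] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.split("\t")

        def cell(name: str) -> str:
            i = col.get(name)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        mi_cell = cell("mi_counts")
        mi: list[CountNotation] = []
        if mi_cell not in _MISSING:
            for token in mi_cell.replace(",", ";").split(";"):
                token = token.strip()
                if not token or token in _MISSING:
                    continue
                try:
                    mi.append(parse_count_notation(token))
                except CountParseError as exc:
                    raise TableFormatError(f"line {lineno}: {exc}") from exc
        m_cell = cell("m_count")
        m_obs = None
        if m_cell not in _MISSING:
            try:
                m_obs = parse_count_notation(m_cell)
            except CountParseError as exc:
                raise TableFormatError(f"line {lineno}: {exc}") from exc
        try:
            records.append(
                ObservedCountRecord(
                    sample_id=cell("sample_id"),
                    line=_normalize_line(cell("line"), lineno),
                    mi_observations=tuple(mi),
                    m_observation=m_obs,
                    printed_x=cell("printed_x") or None,
                    printed_y=cell("printed_y") or None,
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"line {lineno}: {exc}") from exc
    return records


def write_count_table(
    records: Sequence[ObservedCountRecord], target: Union[str, Path, TextIO]
) -> None:
    """Serialize records back to the TSV dialect (canonical token spacing)."""
    with_printed = any(r.printed_x is not None or r.printed_y is not None for r in records)
    columns = list(REQUIRED_COLUMNS) + (list(OPTIONAL_COLUMNS) if with_printed else [])
    out = io.StringIO()
    out.write("\t".join(columns) + "\n")
    for rec in records:
        row = [
            rec.sample_id,
            rec.line,
            "; ".join(o.render() for o in rec.mi_observations) if rec.mi_observations else "–",
            rec.m_observation.render() if rec.m_observation else "–",
        ]
        if with_printed:
            row += [rec.printed_x or "", rec.printed_y or ""]
        out.write("\t".join(row) + "\n")
    if hasattr(target, "write"):
        target.write(out.getvalue())
    else:
        Path(target).write_text(out.getvalue(), encoding="utf-8")
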