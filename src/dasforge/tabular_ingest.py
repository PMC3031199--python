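"""Read GFF and delimiter-separated annotation files into a uniform table.

Two input families are supported: the 9-column General Feature Format
(GFF2/GFF3) and "versatile CSV" — delimiter-separated text whose separator
is auto-detected among comma, semicolon and tab.  Both may carry ``#``
comment lines and ``##key value`` metadata directives (``source-name``,
``source-title``, ``source-maintainer``) that pre-configure source metadata
downstream.
"""

from __future__ import annotations

import csv
import io
import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger("dasforge.ingest")

#: Separators the sniffer will ever propose, in tie-break precedence order.
CANDIDATE_SEPARATORS: tuple[str, ...] = ("\t", ",", ";")

#: Directive keys with a defined meaning; others are kept but warned about.
KNOWN_DIRECTIVES = frozenset({"source-name", "source-title", "source-maintainer"})

GFF_COLUMNS: tuple[str, ...] = (
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
)


class SourceFormat(str, Enum):
    GFF = "GFF"
    DELIMITED = "DELIMITED"


class IngestError(ValueError):
    """Raised when an input file cannot be turned into a dataset."""


@dataclass(frozen=True)
class Dialect:
    """How a delimited file is to be split into cells.

    ``separator`` must be a single character distinct from the first
    character of ``comment_prefix``; auto-detection only ever returns
    comma, semicolon or tab, but any character may be supplied explicitly.
    """

    separator: str
    quote_char: Optional[str] = None
    comment_prefix: str = "#"
    has_header: bool = False

    def __post_init__(self) -> None:
        if len(self.separator) != 1:
            raise IngestError("separator must be exactly one character")
        if self.quote_char is not None and len(self.quote_char) != 1:
            raise IngestError("quote_char must be a single character")
        if self.comment_prefix and self.separator == self.comment_prefix[0]:
            raise IngestError("separator may not equal the comment prefix")


@dataclass
class TabularDataset:
    """Uniform in-memory representation of a parsed annotation file."""

    columns: list[str]
    rows: list[tuple[str, ...]]
    directives: dict[str, str] = field(default_factory=dict)
    source_format: SourceFormat = SourceFormat.DELIMITED
    warnings: list[str] = field(default_factory=list)
    rows_dropped: int = 0

    def __post_init__(self) -> None:
        width = len(self.columns)
        for row in self.rows:
            if len(row) != width:
                raise IngestError(
                    f"row width {len(row)} != column count {width}"
                )


def read_lines(path: str | Path) -> list[str]:
    """Read a text file as UTF-8, replacing undecodable bytes with a warning."""
    raw = Path(path).read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("utf-8", errors="replace")
        logger.warning("%s: undecodable bytes replaced with U+FFFD", path)
    return text.splitlines()


def _is_comment(line: str, prefix: str = "#") -> bool:
    return line.startswith(prefix)


def _is_directive(line: str) -> bool:
    return line.startswith("##")


def _intlike(cell: str) -> bool:
    try:
        int(cell)
    except ValueError:
        return False
    return True


def detect_format(lines: Sequence[str]) -> SourceFormat:
    """Classify input as GFF or generic delimited text.

    GFF is recognised when at least 90% of non-comment lines split on tab
    into exactly 8 or 9 fields with integer start/end columns.
    """
    data = [ln for ln in lines if ln.strip() and not _is_comment(ln)]
    if not data:
        raise IngestError("no data lines")
    gfflike = 0
    for ln in data:
        fields = ln.split("\t")
        if len(fields) in (8, 9) and _intlike(fields[3]) and _intlike(fields[4]):
            gfflike += 1
    return SourceFormat.GFF if gfflike >= 0.9 * len(data) else SourceFormat.DELIMITED


def _count_outside_quotes(line: str, sep: str, quote: str = '"') -> int:
    """Occurrences of ``sep`` in ``line`` that are not inside a quoted span."""
    n = 0
    in_quote = False
    for ch in line:
        if ch == quote:
            in_quote = not in_quote
        elif ch == sep and not in_quote:
            n += 1
    return n


def _numericish(cell: str) -> bool:
    try:
        float(cell)
    except ValueError:
        return False
    return True


def sniff_dialect(lines: Sequence[str], comment_prefix: str = "#") -> Dialect:
    """Detect separator and header presence for a delimited file.

    Among comma, semicolon and tab, keeps candidates occurring (outside
    double quotes) on every non-comment line, and picks the one whose
    per-line count has the lowest variance; ties break tab > comma >
    semicolon.  A header is assumed when the first data row is non-numeric
    at every position where some later row is numeric.
    """
    data = [ln for ln in lines if ln.strip() and not _is_comment(ln, comment_prefix)]
    if not data:
        raise IngestError("no data lines")

    best: Optional[tuple[float, str]] = None
    for sep in CANDIDATE_SEPARATORS:  # precedence order: first wins ties
        counts = [_count_outside_quotes(ln, sep) for ln in data]
        if min(counts) == 0:
            continue
        var = statistics.pvariance(counts)
        if best is None or var < best[0]:
            best = (var, sep)
    if best is None:
        raise IngestError(
            "undetectable separator: none of tab, comma, semicolon "
            "appears on every data line"
        )
    sep = best[1]

    quote = '"' if any('"' in ln for ln in data) else None
    cells = [_split_line(ln, sep, quote) for ln in data]
    has_header = False
    if len(cells) > 1:
        first = cells[0]
        numeric_positions = [
            i for i in range(len(first))
            if any(i < len(row) and _numericish(row[i]) for row in cells[1:])
        ]
        has_header = bool(numeric_positions) and all(
            not _numericish(first[i]) for i in numeric_positions
        )
    return Dialect(separator=sep, quote_char=quote,
                   comment_prefix=comment_prefix, has_header=has_header)


def _split_line(line: str, sep: str, quote: Optional[str]) -> list[str]:
    if quote is None:
        return line.split(sep)
    reader = csv.reader(io.StringIO(line), delimiter=sep, quotechar=quote)
    rows = list(reader)
    return rows[0] if rows else []


def parse_delimited(lines: Sequence[str], dialect: Dialect) -> TabularDataset:
    """Parse delimited text into a dataset under the given dialect.

    Comment lines are excluded, quotes stripped when a quote character is
    set, and ragged rows padded to the modal width with a warning.
    """
    directives = extract_directives(lines)
    warnings: list[str] = []
    raw_rows: list[list[str]] = []
    for ln in lines:
        if not ln.strip() or _is_comment(ln, dialect.comment_prefix):
            continue
        raw_rows.append(_split_line(ln, dialect.separator, dialect.quote_char))
    if not raw_rows:
        raise IngestError("no data rows after comment removal")

    width = Counter(len(r) for r in raw_rows).most_common(1)[0][0]
    rows: list[tuple[str, ...]] = []
    for i, r in enumerate(raw_rows, start=1):
        if len(r) != width:
            warnings.append(f"row {i}: width {len(r)} padded/truncated to {width}")
            r = (r + [""] * width)[:width]
        rows.append(tuple(r))

    if dialect.has_header:
        columns, rows = list(rows[0]), rows[1:]
        if not rows:
            raise IngestError("no data rows after comment removal")
    else:
        columns = [f"col_{i}" for i in range(1, width + 1)]
    return TabularDataset(columns=columns, rows=rows, directives=directives,
                          source_format=SourceFormat.DELIMITED, warnings=warnings)


def parse_gff(lines: Sequence[str]) -> TabularDataset:
    """Parse GFF into the fixed 9-column layout.

    ``##`` directives are routed to :func:`extract_directives`; the GFF
    null token ``.`` is preserved verbatim.  Lines with non-integer
    start/end are dropped with a warning rather than aborting the parse.
    """
    directives = extract_directives(lines)
    warnings: list[str] = []
    rows: list[tuple[str, ...]] = []
    dropped = 0
    for i, ln in enumerate(lines, start=1):
        if not ln.strip() or _is_comment(ln):
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) == 8:
            fields.append("")
        if len(fields) != 9:
            dropped += 1
            warnings.append(f"line {i}: expected 8 or 9 tab-separated fields, "
                            f"got {len(fields)}; dropped")
            continue
        if not (_intlike(fields[3]) and _intlike(fields[4])):
            dropped += 1
            warnings.append(f"line {i}: non-integer start/end; dropped")
            continue
        rows.append(tuple(fields))
    if not rows:
        raise IngestError("no data rows after comment removal")
    return TabularDataset(columns=list(GFF_COLUMNS), rows=rows,
                          directives=directives, source_format=SourceFormat.GFF,
                          warnings=warnings, rows_dropped=dropped)


def extract_directives(lines: Iterable[str]) -> dict[str, str]:
    """Collect ``##key value`` metadata directives; later duplicates win.

    Keys are lower-cased.  ``key=value`` is accepted as an alternative to
    whitespace separation.  Unknown keys are kept and warned about.
    """
    out: dict[str, str] = {}
    for ln in lines:
        if not _is_directive(ln):
            continue
        body = ln[2:].strip()
        if not body:
            continue
        if "=" in body.split(None, 1)[0]:
            key, _, value = body.partition("=")
        else:
            key, _, value = body.partition(" ")
        key = key.strip().lower()
        if not key:
            continue
        if key not in KNOWN_DIRECTIVES:
            logger.warning("unknown metadata directive %r retained", key)
        out[key] = value.strip()
    return out


def load_dataset(
    lines: Sequence[str],
    fmt: Optional[SourceFormat] = None,
    dialect: Optional[Dialect] = None,
) -> TabularDataset:
    """One-call ingest: detect format, sniff dialect if needed, parse."""
    fmt = fmt or detect_format(lines)
    if fmt is SourceFormat.GFF:
        return parse_gff(lines)
    return parse_delimited(lines, dialect or sniff_dialect(lines))
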