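"""Deterministic generators for every input the tests and examples need.

All generators are pure functions of their arguments including the seed,
so any dataset can be regenerated byte-for-byte.  The ontology-term table
and coordinate-system registry are tiny curated subsets with realistic
accession syntax — enough to exercise cvId and coordinate-system
plumbing without shipping real ontology releases.
"""

from __future__ import annotations

import random
from typing import Optional, Sequence

from .tabular_ingest import Dialect

MAX_POSITION = 1_000_000
FEATURE_TYPES = ("gene", "exon", "repeat_region")
STRANDS = ("+", "-", ".")

#: term_id \t term_name \t ontology — spans all four recommended ontologies.
TERM_TABLE_ROWS: tuple[tuple[str, str, str], ...] = (
    ("SO:0000704", "gene", "SO"),
    ("SO:0000147", "exon", "SO"),
    ("SO:0000657", "repeat_region", "SO"),
    ("SO:0000316", "CDS", "SO"),
    ("BS:00063", "metal_contact", "BS"),
    ("BS:00173", "annotated_domain", "BS"),
    ("MOD:00046", "O-phospho-L-serine", "MOD"),
    ("ECO:0000006", "experimental_evidence", "ECO"),
    ("ECO:0000044", "sequence_similarity_evidence", "ECO"),
)

#: uri \t authority \t version \t species \t taxid \t content_type
COORD_REGISTRY_ROWS: tuple[tuple[str, str, str, str, str, str], ...] = (
    ("http://www.dasregistry.org/coordsys/CS_DS40",
     "GRCh", "37", "Homo sapiens", "9606", "Chromosome"),
    ("http://www.dasregistry.org/coordsys/CS_DS5",
     "NCBIM", "37", "Mus musculus", "10090", "Chromosome"),
    ("http://www.dasregistry.org/coordsys/CS_DS6",
     "UniProt", "", "", "", "Protein Sequence"),
    ("http://www.dasregistry.org/coordsys/CS_DS108",
     "Zv", "9", "Danio rerio", "7955", "Chromosome"),
)


def _interval(rng: random.Random) -> tuple[int, int]:
    a = rng.randint(1, MAX_POSITION)
    b = rng.randint(1, MAX_POSITION)
    return (a, b) if a <= b else (b, a)


def gen_gff(n: int, segments: Sequence[str] = ("chr1", "chr2", "chr3"),
            seed: int = 0, directives: Optional[dict[str, str]] = None,
            comment_every: int = 0) -> str:
    """Generate valid 9-column GFF text with ``n`` features.

    Starts and ends are drawn uniformly in [1, 10^6] with start <= end;
    types come from {gene, exon, repeat_region} and strands from
    {+, -, .}.  ``directives`` are emitted as ``##key value`` header
    lines; ``comment_every`` > 0 interleaves a ``#`` comment before
    every k-th feature line.  Same arguments -> identical bytes.
    """
    rng = random.Random(seed)
    lines: list[str] = []
    for key, value in (directives or {}).items():
        lines.append(f"##{key} {value}")
    for i in range(1, n + 1):
        if comment_every and (i - 1) % comment_every == 0:
            lines.append(f"# comment before feature {i}")
        start, end = _interval(rng)
        ftype = rng.choice(FEATURE_TYPES)
        strand = rng.choice(STRANDS)
        score = "." if rng.random() < 0.2 else f"{rng.random():.3f}"
        lines.append("\t".join([
            rng.choice(list(segments)), "dasforge_sim", ftype,
            str(start), str(end), score, strand, ".", f"ID=f{i}",
        ]))
    return "\n".join(lines) + "\n"


def gen_csv(n: int, dialect: Optional[Dialect] = None, seed: int = 0,
            segments: Sequence[str] = ("chr1", "chr2")) -> str:
    """Generate delimited annotation text honouring the declared dialect.

    Columns are drawn from heuristically mappable names
    (chromosome, start, end, type, score, strand); the header row is
    emitted only when the dialect declares one, and cells are quoted when
    a quote character is declared.  Seed-deterministic.
    """
    dialect = dialect or Dialect(separator=",", has_header=True)
    rng = random.Random(seed)
    sep, quote = dialect.separator, dialect.quote_char

    def cell(value: str, quotable: bool) -> str:
        if quote and quotable:
            return f"{quote}{value}{quote}"
        return value

    lines: list[str] = []
    header = ("chromosome", "start", "end", "type", "score", "strand")
    if dialect.has_header:
        lines.append(sep.join(cell(h, True) for h in header))
    for _ in range(n):
        start, end = _interval(rng)
        row = [
            cell(rng.choice(list(segments)), True),
            str(start), str(end),
            cell(rng.choice(FEATURE_TYPES), True),
            f"{rng.random():.3f}",
            rng.choice(("+", "-")),
        ]
        lines.append(sep.join(row))
    return "\n".join(lines) + "\n"


def gen_term_table() -> str:
    """Tab-separated (term_id, term_name, ontology) ontology-term fixture."""
    return "\n".join("\t".join(row) for row in TERM_TABLE_ROWS) + "\n"


def gen_coord_registry() -> str:
    """Tab-separated coordinate-system registry fixture (includes GRCh37)."""
    return "\n".join("\t".join(row) for row in COORD_REGISTRY_ROWS) + "\n"
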