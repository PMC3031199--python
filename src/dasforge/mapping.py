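"""Link file fields to DAS concepts and materialise annotation records.

A :class:`FieldMapping` describes how columns of a parsed table feed the
DAS feature model: one-to-one, one-to-many (a column feeding several
concepts) and many-to-many (several columns feeding one concept) are all
expressible.  Defaults fill a concept per-row whenever the mapped cells
are empty or the GFF null token ``.``.  Ontology-term associations
(cvId values for types and methods) are remembered per user and local
identifier so that re-used identifiers are annotated consistently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .tabular_ingest import SourceFormat, TabularDataset

logger = logging.getLogger("dasforge.mapping")

GFF_NULL = "."


class MappingError(ValueError):
    """Raised when a mapping cannot be applied at all."""


class DasConcept(str, Enum):
    """The closed set of DAS feature fields a file column can feed."""

    SEGMENT_ID = "SEGMENT_ID"
    START = "START"
    END = "END"
    TYPE = "TYPE"
    METHOD = "METHOD"
    SCORE = "SCORE"
    ORIENTATION = "ORIENTATION"
    PHASE = "PHASE"
    FEATURE_ID = "FEATURE_ID"
    LABEL = "LABEL"
    NOTE = "NOTE"
    LINK = "LINK"


#: The trio that every DAS feature must resolve, by rule or by default.
REQUIRED_CONCEPTS = (DasConcept.SEGMENT_ID, DasConcept.START, DasConcept.END)

#: Concepts that take a single value (first non-empty mapped cell wins);
#: NOTE and LINK aggregate instead.
_SINGLE_VALUED = frozenset(DasConcept) - {DasConcept.NOTE, DasConcept.LINK}


@dataclass
class FieldMapping:
    rules: list[tuple[str, DasConcept]] = field(default_factory=list)
    defaults: dict[DasConcept, str] = field(default_factory=dict)
    #: per-default fill policy; only absent_only exists (fill when the
    #: row's mapped cells are empty or ".")
    fill_mode: str = "absent_only"

    def __post_init__(self) -> None:
        for concept in (DasConcept.START, DasConcept.END):
            n = sum(1 for _, c in self.rules if c is concept)
            if n > 1:
                raise MappingError(f"{concept.value} mapped by {n} rules; at most one allowed")

    def columns_for(self, concept: DasConcept) -> list[str]:
        return [col for col, c in self.rules if c is concept]


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    term_name: str
    ontology: str  # SO | BS | MOD | ECO


@dataclass(frozen=True)
class OntologyTermAssociation:
    namespace_user: str
    local_identifier: str
    term: OntologyTerm


class TermStore:
    """Per-user memory of ontology-term choices, backed by a closed vocabulary.

    ``vocabulary`` maps term_id -> :class:`OntologyTerm`; remembering a
    term not in the vocabulary is an error, mirroring selection from a
    fixed ontology subset.
    """

    def __init__(self, vocabulary: dict[str, OntologyTerm]):
        self.vocabulary = dict(vocabulary)
        self._assoc: dict[tuple[str, str], OntologyTerm] = {}

    @classmethod
    def from_table(cls, text: str, sep: str = "\t") -> "TermStore":
        """Build a store from a 3-column (term_id, term_name, ontology) table."""
        vocab: dict[str, OntologyTerm] = {}
        for ln in text.splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            term_id, term_name, ontology = ln.split(sep)
            vocab[term_id] = OntologyTerm(term_id, term_name, ontology)
        return cls(vocab)


def remember_term(store: TermStore, namespace_user: str,
                  local_identifier: str, term: OntologyTerm | str) -> TermStore:
    """Associate an ontology term with (user, local identifier); last write wins."""
    term_id = term.term_id if isinstance(term, OntologyTerm) else term
    if term_id not in store.vocabulary:
        raise MappingError(f"unknown term {term_id!r}")
    store._assoc[(namespace_user, local_identifier)] = store.vocabulary[term_id]
    return store


def recall_term(store: TermStore, namespace_user: str,
                local_identifier: str) -> Optional[OntologyTerm]:
    return store._assoc.get((namespace_user, local_identifier))


@dataclass
class AnnotationRecord:
    """One positioned feature on a segment, 1-based inclusive coordinates."""

    segment_id: str
    start: int
    end: int
    type_id: str
    method_id: str
    feature_id: str
    type_cv_id: Optional[str] = None
    method_cv_id: Optional[str] = None
    score: Optional[float] = None
    orientation: str = "0"
    phase: str = "-"
    label: Optional[str] = None
    notes: list[str] = field(default_factory=list)
    links: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise MappingError(
                f"invalid interval [{self.start}, {self.end}] on {self.segment_id}")
        if self.orientation not in ("+", "-", "0"):
            raise MappingError(f"invalid orientation {self.orientation!r}")
        if self.phase not in ("0", "1", "2", "-"):
            raise MappingError(f"invalid phase {self.phase!r}")


# Canonical GFF column -> concept mapping; FEATURE_ID comes from the
# attributes column's ID key, handled specially in apply_mapping.
GFF_CANONICAL_RULES: list[tuple[str, DasConcept]] = [
    ("seqid", DasConcept.SEGMENT_ID),
    ("type", DasConcept.TYPE),
    ("start", DasConcept.START),
    ("end", DasConcept.END),
    ("score", DasConcept.SCORE),
    ("strand", DasConcept.ORIENTATION),
    ("phase", DasConcept.PHASE),
    ("source", DasConcept.METHOD),
    ("attributes", DasConcept.FEATURE_ID),
]

# Case-insensitive column-name patterns for delimited files.  First match
# wins; a single-valued concept is proposed at most once.
HEURISTIC_PATTERNS: list[tuple[str, DasConcept]] = [
    (r"chrom|chromosome|seq.?id|seqname|segment", DasConcept.SEGMENT_ID),
    (r"start|begin|from", DasConcept.START),
    (r"end|stop|to", DasConcept.END),
    (r"type|feature", DasConcept.TYPE),
    (r"method|source", DasConcept.METHOD),
    (r"score|value", DasConcept.SCORE),
    (r"strand|orientation", DasConcept.ORIENTATION),
    (r"phase|frame", DasConcept.PHASE),
    (r"id|name", DasConcept.FEATURE_ID),
    (r"label", DasConcept.LABEL),
]


def propose_mapping(dataset: TabularDataset) -> FieldMapping:
    """Heuristic mapping proposal.

    GFF datasets get the fixed canonical mapping.  For delimited files
    column names are matched case-insensitively against a pattern table;
    unmatched columns become NOTE so no data is silently discarded.
    """
    if dataset.source_format is SourceFormat.GFF:
        return FieldMapping(rules=list(GFF_CANONICAL_RULES))
    rules: list[tuple[str, DasConcept]] = []
    taken: set[DasConcept] = set()
    for col in dataset.columns:
        concept = None
        for pattern, cand in HEURISTIC_PATTERNS:
            if re.fullmatch(pattern, col, flags=re.IGNORECASE):
                concept = cand
                break
        if concept is None or (concept in _SINGLE_VALUED and concept in taken):
            rules.append((col, DasConcept.NOTE))
        else:
            rules.append((col, concept))
            taken.add(concept)
    return FieldMapping(rules=rules)


def validate_mapping(mapping: FieldMapping, dataset: TabularDataset) -> list[str]:
    """Return a list of issues; empty means the mapping is applicable."""
    issues: list[str] = []
    known = set(dataset.columns)
    for col, concept in mapping.rules:
        if col not in known:
            issues.append(f"unknown column {col!r} mapped to {concept.value}")
    for concept in REQUIRED_CONCEPTS:
        has_rule = any(col in known for col, c in mapping.rules if c is concept)
        if not has_rule and concept not in mapping.defaults:
            issues.append(f"required concept {concept.value} has no rule or default")
    return issues


def _gff_attribute(attributes: str, key: str) -> Optional[str]:
    """Extract one key from a GFF attributes cell (GFF3 '=' or GFF2 space)."""
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            k, _, v = chunk.partition("=")
        else:
            k, _, v = chunk.partition(" ")
        if k.strip() == key:
            return v.strip().strip('"')
    return None


def _cell_values(row: dict[str, str], mapping: FieldMapping,
                 concept: DasConcept, is_gff: bool) -> list[str]:
    """Non-empty mapped cell values for a concept, in rule order."""
    values: list[str] = []
    for col in mapping.columns_for(concept):
        cell = row.get(col, "")
        if is_gff and col == "attributes" and concept is DasConcept.FEATURE_ID:
            cell = _gff_attribute(cell, "ID") or _gff_attribute(cell, "id") or ""
        if cell and cell != GFF_NULL:
            values.append(cell)
    return values


def apply_mapping(
    dataset: TabularDataset,
    mapping: FieldMapping,
    term_store: Optional[TermStore] = None,
    *,
    source_id: str = "source",
    namespace_user: str = "anonymous",
) -> tuple[list[AnnotationRecord], list[str]]:
    """Materialise annotation records from a dataset under a mapping.

    Every input row yields exactly one record or one row issue.  Defaults
    fill a concept only when the row's mapped cells are empty or ".";
    strand "." becomes orientation "0"; a missing feature id is
    synthesised as ``<source_id>_f<row_number>``; cvIds are attached from
    the term store when an association exists for the row's type or
    method identifier.
    """
    issues = validate_mapping(mapping, dataset)
    if issues:
        raise MappingError("mapping invalid: " + "; ".join(issues))

    is_gff = dataset.source_format is SourceFormat.GFF
    records: list[AnnotationRecord] = []
    row_issues: list[str] = []
    seen_ids: set[str] = set()

    for rownum, cells in enumerate(dataset.rows, start=1):
        row = dict(zip(dataset.columns, cells))

        def value_of(concept: DasConcept) -> Optional[str]:
            vals = _cell_values(row, mapping, concept, is_gff)
            if vals:
                return vals[0]
            return mapping.defaults.get(concept)

        try:
            seg = value_of(DasConcept.SEGMENT_ID)
            raw_start = value_of(DasConcept.START)
            raw_end = value_of(DasConcept.END)
            if not seg or raw_start is None or raw_end is None:
                raise MappingError("missing segment/start/end")
            try:
                start, end = int(raw_start), int(raw_end)
            except ValueError:
                raise MappingError(
                    f"non-integer coordinates ({raw_start!r}, {raw_end!r})")

            strand = value_of(DasConcept.ORIENTATION) or "0"
            orientation = "0" if strand == GFF_NULL else strand
            phase = value_of(DasConcept.PHASE) or "-"

            raw_score = value_of(DasConcept.SCORE)
            score = None
            if raw_score not in (None, "", GFF_NULL):
                try:
                    score = float(raw_score)
                except ValueError:
                    raise MappingError(f"non-numeric score {raw_score!r}")

            type_id = value_of(DasConcept.TYPE) or "feature"
            method_id = value_of(DasConcept.METHOD) or "unknown"
            feature_id = value_of(DasConcept.FEATURE_ID) or f"{source_id}_f{rownum}"
            if feature_id in seen_ids:
                logger.warning("duplicate feature id %r; suffixed with row number",
                               feature_id)
                feature_id = f"{feature_id}_{rownum}"
            label = value_of(DasConcept.LABEL)

            notes = [f"{col}: {row[col]}"
                     for col in mapping.columns_for(DasConcept.NOTE)
                     if row.get(col) and row[col] != GFF_NULL]
            if not notes and DasConcept.NOTE in mapping.defaults:
                notes = [mapping.defaults[DasConcept.NOTE]]
            links = [(href, href)
                     for href in _cell_values(row, mapping, DasConcept.LINK, is_gff)]
            if not links and DasConcept.LINK in mapping.defaults:
                links = [(mapping.defaults[DasConcept.LINK],
                          mapping.defaults[DasConcept.LINK])]

            type_cv = method_cv = None
            if term_store is not None:
                t = recall_term(term_store, namespace_user, type_id)
                type_cv = t.term_id if t else None
                m = recall_term(term_store, namespace_user, method_id)
                method_cv = m.term_id if m else None

            record = AnnotationRecord(
                segment_id=seg, start=start, end=end,
                type_id=type_id, type_cv_id=type_cv,
                method_id=method_id, method_cv_id=method_cv,
                score=score, orientation=orientation, phase=phase,
                feature_id=feature_id, label=label, notes=notes, links=links,
            )
        except MappingError as exc:
            row_issues.append(f"row {rownum}: {exc}")
            continue
        seen_ids.add(record.feature_id)
        records.append(record)

    if not records:
        raise MappingError("no valid features")
    return records, row_issues
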