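"""Per-source isolated persistence and interval queries.

Each DAS source owns exactly six SQLite tables named
``<owner>__<source_id>__{meta,segments,types,methods,features,annexes}``;
no table is ever shared between sources, so deleting a source is a set of
whole-table drops and writes for different sources never touch the same
table.  Sources are discovered by scanning for ``*__meta`` tables and
reading owner/source id from their contents, so there is no central
catalog to keep in sync.

Coordinates are 1-based inclusive end-to-end (GFF and DAS agree on this),
so no conversion layer exists anywhere in the package.
"""

from __future__ import annotations

import hashlib
import re
import sqlite3
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .mapping import AnnotationRecord

_ID_RE = re.compile(r"[A-Za-z0-9_-]+\Z")
TABLE_SUFFIXES = ("meta", "segments", "types", "methods", "features", "annexes")


class StoreError(ValueError):
    """Raised for invalid store operations (duplicate ids, unknown sources...)."""


@dataclass(frozen=True)
class CoordinateSystem:
    """Species + assembly (+ content type) a source's segment ids refer to."""

    uri: str
    authority: str
    version: str
    species: str
    taxid: Optional[int] = None
    content_type: str = "Chromosome"

    def __post_init__(self) -> None:
        if self.taxid is not None and not self.species:
            raise StoreError("species required when taxid is set")


@dataclass
class SourceDefinition:
    owner: str
    source_id: str
    title: str = ""
    description: str = ""
    maintainer_email: str = ""
    coordinate_system: Optional[CoordinateSystem] = None
    listed: bool = True
    created_at: float = 0.0
    expires_at: Optional[float] = None

    def __post_init__(self) -> None:
        for name, value in (("owner", self.owner), ("source_id", self.source_id)):
            if not _ID_RE.match(value or ""):
                raise StoreError(f"{name} must match [A-Za-z0-9_-]+, got {value!r}")
        if not self.title:
            self.title = self.source_id


@dataclass(frozen=True)
class SegmentQuery:
    """A DAS features request: segment id, optional 1-based inclusive range."""

    segment_id: str
    start: Optional[int] = None
    stop: Optional[int] = None
    type_filter: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.start is None) != (self.stop is None):
            raise StoreError("start and stop must both be present or both absent")
        if self.start is not None:
            if self.start < 1 or self.stop < self.start:
                raise StoreError(
                    f"invalid range {self.start},{self.stop} (1-based inclusive)")


@dataclass
class FeatureQueryResult:
    """Records matching one segment query, plus segment-level context."""

    query: SegmentQuery
    records: list[AnnotationRecord]
    segment_known: bool
    segment_start: Optional[int] = None
    segment_stop: Optional[int] = None


def load_coordinate_registry(text: str, sep: str = "\t") -> dict[str, CoordinateSystem]:
    """Parse a (uri, authority, version, species, taxid, content_type) table."""
    registry: dict[str, CoordinateSystem] = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        uri, authority, version, species, taxid, content_type = ln.split(sep)
        registry[uri] = CoordinateSystem(
            uri=uri, authority=authority, version=version, species=species,
            taxid=int(taxid) if taxid else None, content_type=content_type)
    return registry


class SourceStore:
    """All sources in one embedded SQLite file (or in-memory database)."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute("PRAGMA foreign_keys = ON")

    def close(self) -> None:
        self._conn.close()

    # -- naming ----------------------------------------------------------

    @staticmethod
    def _prefix(owner: str, source_id: str) -> str:
        return f"{owner}__{source_id}__"

    def _tables(self, owner: str, source_id: str) -> dict[str, str]:
        p = self._prefix(owner, source_id)
        return {s: p + s for s in TABLE_SUFFIXES}

    def _exists(self, owner: str, source_id: str) -> bool:
        cur = self._conn.execute(
            "SELECT 1 FROM sqlite_master WHERE type='table' AND name=?",
            (self._prefix(owner, source_id) + "meta",))
        return cur.fetchone() is not None

    def _require(self, owner: str, source_id: str) -> None:
        if not self._exists(owner, source_id):
            raise StoreError(f"unknown source {owner}/{source_id}")

    def table_census(self) -> int:
        """Number of per-source storage tables currently present."""
        cur = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'")
        names = [r[0] for r in cur.fetchall()]
        return sum(1 for n in names
                   if any(n.endswith("__" + s) for s in TABLE_SUFFIXES))

    # -- lifecycle -------------------------------------------------------

    def create_source(self, definition: SourceDefinition,
                      records: Sequence[AnnotationRecord]) -> SourceDefinition:
        """Create the six tables for a new source and load its records."""
        if not records:
            raise StoreError("no valid features")
        if self._exists(definition.owner, definition.source_id):
            raise StoreError(
                f"source exists: {definition.owner}/{definition.source_id}")
        if not definition.created_at:
            definition = replace(definition, created_at=time.time())
        t = self._tables(definition.owner, definition.source_id)
        q = lambda name: '"' + name + '"'
        with self._conn:
            self._conn.execute(
                f"CREATE TABLE {q(t['meta'])} (key TEXT PRIMARY KEY, value TEXT)")
            self._conn.execute(
                f"CREATE TABLE {q(t['segments'])} (segment_id TEXT PRIMARY KEY,"
                " min_start INTEGER, max_end INTEGER, feature_count INTEGER)")
            self._conn.execute(
                f"CREATE TABLE {q(t['types'])} (type_id TEXT, type_cv_id TEXT)")
            self._conn.execute(
                f"CREATE TABLE {q(t['methods'])} (method_id TEXT, method_cv_id TEXT)")
            self._conn.execute(
                f"CREATE TABLE {q(t['features'])} (feature_id TEXT PRIMARY KEY,"
                " segment_id TEXT, start INTEGER, end INTEGER,"
                " type_id TEXT, type_cv_id TEXT, method_id TEXT, method_cv_id TEXT,"
                " score REAL, orientation TEXT, phase TEXT, label TEXT)")
            self._conn.execute(
                f"CREATE TABLE {q(t['annexes'])} (feature_id TEXT, kind TEXT,"
                " value TEXT, href TEXT)")
            self._write_meta(t["meta"], definition, records)
            self._write_records(t, records)
        return definition

    def _write_meta(self, meta_table: str, definition: SourceDefinition,
                    records: Sequence[AnnotationRecord]) -> None:
        digest = hashlib.sha1(
            "\n".join(f"{r.feature_id}:{r.segment_id}:{r.start}:{r.end}"
                      for r in records).encode()).hexdigest()[:12]
        cs = definition.coordinate_system
        pairs = {
            "owner": definition.owner,
            "source_id": definition.source_id,
            "title": definition.title,
            "description": definition.description,
            "maintainer_email": definition.maintainer_email,
            "listed": "1" if definition.listed else "0",
            "created_at": repr(definition.created_at),
            "expires_at": "" if definition.expires_at is None
                          else repr(definition.expires_at),
            "version": digest,
            "cs_uri": cs.uri if cs else "",
            "cs_authority": cs.authority if cs else "",
            "cs_version": cs.version if cs else "",
            "cs_species": cs.species if cs else "",
            "cs_taxid": str(cs.taxid) if cs and cs.taxid is not None else "",
            "cs_content_type": cs.content_type if cs else "",
        }
        self._conn.executemany(
            f'INSERT OR REPLACE INTO "{meta_table}" (key, value) VALUES (?, ?)',
            list(pairs.items()))

    def _write_records(self, t: dict[str, str],
                       records: Sequence[AnnotationRecord]) -> None:
        self._conn.executemany(
            f'INSERT INTO "{t["features"]}" VALUES (?,?,?,?,?,?,?,?,?,?,?,?)',
            [(r.feature_id, r.segment_id, r.start, r.end, r.type_id,
              r.type_cv_id, r.method_id, r.method_cv_id, r.score,
              r.orientation, r.phase, r.label) for r in records])
        segs: dict[str, tuple[int, int, int]] = {}
        for r in records:
            lo, hi, n = segs.get(r.segment_id, (r.start, r.end, 0))
            segs[r.segment_id] = (min(lo, r.start), max(hi, r.end), n + 1)
        self._conn.executemany(
            f'INSERT INTO "{t["segments"]}" VALUES (?,?,?,?)',
            [(sid, lo, hi, n) for sid, (lo, hi, n) in segs.items()])
        self._conn.executemany(
            f'INSERT INTO "{t["types"]}" VALUES (?,?)',
            sorted({(r.type_id, r.type_cv_id) for r in records},
                   key=lambda x: (x[0], x[1] or "")))
        self._conn.executemany(
            f'INSERT INTO "{t["methods"]}" VALUES (?,?)',
            sorted({(r.method_id, r.method_cv_id) for r in records},
                   key=lambda x: (x[0], x[1] or "")))
        annexes = []
        for r in records:
            annexes += [(r.feature_id, "note", note, None) for note in r.notes]
            annexes += [(r.feature_id, "link", text, href) for href, text in r.links]
        if annexes:
            self._conn.executemany(
                f'INSERT INTO "{t["annexes"]}" VALUES (?,?,?,?)', annexes)

    def delete_source(self, owner: str, source_id: str) -> None:
        """Drop all six tables of one source; others are untouched."""
        self._require(owner, source_id)
        with self._conn:
            for table in self._tables(owner, source_id).values():
                self._conn.execute(f'DROP TABLE IF EXISTS "{table}"')

    def replace_source_data(self, owner: str, source_id: str,
                            records: Sequence[AnnotationRecord]) -> SourceDefinition:
        """Rewrite feature/segment/type/method/annex data; meta is preserved."""
        self._require(owner, source_id)
        if not records:
            raise StoreError("no valid features")
        t = self._tables(owner, source_id)
        with self._conn:
            for suffix in ("features", "segments", "types", "methods", "annexes"):
                self._conn.execute(f'DELETE FROM "{t[suffix]}"')
            self._write_records(t, records)
        return self.get_source(owner, source_id)

    # -- introspection ---------------------------------------------------

    def _meta(self, owner: str, source_id: str) -> dict[str, str]:
        t = self._prefix(owner, source_id) + "meta"
        cur = self._conn.execute(f'SELECT key, value FROM "{t}"')
        return dict(cur.fetchall())

    def get_source(self, owner: str, source_id: str) -> SourceDefinition:
        self._require(owner, source_id)
        m = self._meta(owner, source_id)
        cs = None
        if m.get("cs_uri"):
            cs = CoordinateSystem(
                uri=m["cs_uri"], authority=m["cs_authority"],
                version=m["cs_version"], species=m["cs_species"],
                taxid=int(m["cs_taxid"]) if m["cs_taxid"] else None,
                content_type=m["cs_content_type"] or "Chromosome")
        return SourceDefinition(
            owner=m["owner"], source_id=m["source_id"], title=m["title"],
            description=m["description"], maintainer_email=m["maintainer_email"],
            coordinate_system=cs, listed=m["listed"] == "1",
            created_at=float(m["created_at"] or 0),
            expires_at=float(m["expires_at"]) if m.get("expires_at") else None)

    def source_version(self, owner: str, source_id: str) -> str:
        """Opaque content hash used as the DAS segment/source version."""
        return self._meta(owner, source_id).get("version", "0")

    def _all_source_keys(self) -> list[tuple[str, str]]:
        cur = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'"
            " AND name LIKE '%__meta'")
        keys = []
        for (name,) in cur.fetchall():
            row = dict(self._conn.execute(
                f'SELECT key, value FROM "{name}"'
                " WHERE key IN ('owner','source_id')").fetchall())
            if "owner" in row and "source_id" in row:
                keys.append((row["owner"], row["source_id"]))
        return sorted(keys)

    def list_sources(self, owner: Optional[str] = None,
                     now: Optional[float] = None) -> list[SourceDefinition]:
        """Global listing (listed, unexpired sources) or one owner's full list."""
        now = time.time() if now is None else now
        out = []
        for o, sid in self._all_source_keys():
            defn = self.get_source(o, sid)
            if owner is None:
                if not defn.listed:
                    continue
                if defn.expires_at is not None and defn.expires_at < now:
                    continue
            elif o != owner:
                continue
            out.append(defn)
        return out

    # -- queries ---------------------------------------------------------

    def _row_to_record(self, row: tuple, annexes: dict) -> AnnotationRecord:
        (fid, seg, start, end, type_id, type_cv, method_id, method_cv,
         score, orientation, phase, label) = row
        notes, links = annexes.get(fid, ([], []))
        return AnnotationRecord(
            segment_id=seg, start=start, end=end, type_id=type_id,
            type_cv_id=type_cv, method_id=method_id, method_cv_id=method_cv,
            score=score, orientation=orientation, phase=phase,
            feature_id=fid, label=label, notes=list(notes), links=list(links))

    def _annexes_for(self, t: dict[str, str],
                     feature_ids: Iterable[str]) -> dict:
        out: dict[str, tuple[list, list]] = {}
        ids = list(feature_ids)
        if not ids:
            return out
        marks = ",".join("?" * len(ids))
        cur = self._conn.execute(
            f'SELECT feature_id, kind, value, href FROM "{t["annexes"]}"'
            f" WHERE feature_id IN ({marks})", ids)
        for fid, kind, value, href in cur.fetchall():
            notes, links = out.setdefault(fid, ([], []))
            if kind == "note":
                notes.append(value)
            else:
                links.append((href, value))
        return out

    def query_features(self, owner: str, source_id: str,
                       query: SegmentQuery) -> FeatureQueryResult:
        """Features on a segment overlapping the (optional) 1-based range.

        Overlap is inclusive: a record matches when record.start <= stop
        and record.end >= start.  An unknown segment yields an empty,
        flagged result so the protocol layer can emit ERRORSEGMENT.
        """
        self._require(owner, source_id)
        t = self._tables(owner, source_id)
        seg = self._conn.execute(
            f'SELECT min_start, max_end FROM "{t["segments"]}"'
            " WHERE segment_id=?", (query.segment_id,)).fetchone()
        if seg is None:
            return FeatureQueryResult(query=query, records=[],
                                      segment_known=False)
        sql = (f'SELECT * FROM "{t["features"]}" WHERE segment_id=?')
        args: list = [query.segment_id]
        if query.start is not None:
            sql += " AND start<=? AND end>=?"
            args += [query.stop, query.start]
        if query.type_filter is not None:
            sql += " AND (type_id=? OR type_cv_id=?)"
            args += [query.type_filter, query.type_filter]
        sql += " ORDER BY start, end, feature_id"
        rows = self._conn.execute(sql, args).fetchall()
        annexes = self._annexes_for(t, (r[0] for r in rows))
        return FeatureQueryResult(
            query=query,
            records=[self._row_to_record(r, annexes) for r in rows],
            segment_known=True, segment_start=seg[0], segment_stop=seg[1])

    def aggregate_types(self, owner: str, source_id: str,
                        query: Optional[SegmentQuery] = None
                        ) -> list[tuple[str, Optional[str], int]]:
        """(type_id, type_cv_id, count) over optionally range-restricted features."""
        self._require(owner, source_id)
        t = self._tables(owner, source_id)
        sql = (f'SELECT type_id, type_cv_id, COUNT(*) FROM "{t["features"]}"')
        args: list = []
        clauses: list[str] = []
        if query is not None:
            clauses.append("segment_id=?")
            args.append(query.segment_id)
            if query.start is not None:
                clauses.append("start<=? AND end>=?")
                args += [query.stop, query.start]
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " GROUP BY type_id, type_cv_id ORDER BY COUNT(*) DESC, type_id"
        return [tuple(r) for r in self._conn.execute(sql, args).fetchall()]

    def entry_points(self, owner: str,
                     source_id: str) -> list[tuple[str, int, int]]:
        """One (segment_id, 1, max end seen) row per distinct segment."""
        self._require(owner, source_id)
        t = self._tables(owner, source_id)
        cur = self._conn.execute(
            f'SELECT segment_id, max_end FROM "{t["segments"]}"'
            " ORDER BY segment_id")
        return [(sid, 1, stop) for sid, stop in cur.fetchall()]
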