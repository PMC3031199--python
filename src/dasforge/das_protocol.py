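"""DAS 1.6 request parsing and XML document rendering.

Renders the SOURCES, FEATURES, TYPES and ENTRY_POINTS documents and
attaches the protocol headers (``X-DAS-Version: DAS/1.6`` on every
response, including errors).  Structural compliance is asserted by the
test suite re-parsing each document rather than by DTD validation: the
required root and child elements of each command are checked directly.

Semantic annotation is carried through the DAS 1.6 ``cvId`` attribute on
TYPE and METHOD elements whenever an ontology accession is known for a
feature's type or method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from lxml import etree

from .mapping import AnnotationRecord
from .source_store import (FeatureQueryResult, SegmentQuery, SourceDefinition,
                           StoreError)

DAS_VERSION = "DAS/1.6"
CAPABILITIES = ("sources/1.0; features/1.6; types/1.6; entry_points/1.6; "
                "error-segment/1.0")
XML_CONTENT_TYPE = "text/xml; charset=utf-8"

#: protocol error kind -> HTTP status
_ERROR_STATUS = {
    "unknown source": 404,
    "not found": 404,
    "bad command": 400,
    "unknown command": 400,
    "bad command arguments": 400,
}


class ProtocolError(Exception):
    """A DAS-level error carrying the kind string used for status mapping."""

    def __init__(self, kind: str, detail: str = ""):
        self.kind = kind
        self.detail = detail
        super().__init__(f"{kind}: {detail}" if detail else kind)


def das_headers() -> dict[str, str]:
    return {"X-DAS-Version": DAS_VERSION, "X-DAS-Capabilities": CAPABILITIES}


def protocol_error(kind: str) -> tuple[int, dict[str, str]]:
    """HTTP status and headers for a DAS error response."""
    return _ERROR_STATUS.get(kind, 500), das_headers()


@dataclass
class DasDocument:
    command: str
    body: etree._Element
    headers: dict[str, str] = field(default_factory=das_headers)

    def to_xml(self) -> bytes:
        return etree.tostring(self.body, xml_declaration=True,
                              encoding="UTF-8", pretty_print=True)


def parse_features_params(
        params: Mapping[str, Sequence[str]]) -> list[SegmentQuery]:
    """Turn features-command query parameters into segment queries.

    Each ``segment`` value is ``ID`` or ``ID:start,stop`` (1-based
    inclusive); the optional ``type`` parameter filters every query.
    """
    segments = list(params.get("segment", []))
    if not segments:
        raise ProtocolError("bad command arguments", "no segment parameter")
    types = list(params.get("type", []))
    type_filter = types[0] if types else None
    queries = []
    for raw in segments:
        sid, _, rng = raw.partition(":")
        if not sid:
            raise ProtocolError("bad command arguments", f"empty segment in {raw!r}")
        start = stop = None
        if rng:
            start_s, sep, stop_s = rng.partition(",")
            try:
                start, stop = int(start_s), int(stop_s)
            except ValueError:
                raise ProtocolError("bad command arguments",
                                    f"non-integer range in {raw!r}")
            if not sep or start < 1 or stop < start:
                raise ProtocolError("bad command arguments",
                                    f"invalid range in {raw!r}")
        try:
            queries.append(SegmentQuery(segment_id=sid, start=start, stop=stop,
                                        type_filter=type_filter))
        except StoreError as exc:
            raise ProtocolError("bad command arguments", str(exc))
    return queries


def _feature_element(parent: etree._Element, rec: AnnotationRecord) -> None:
    feat = etree.SubElement(parent, "FEATURE", id=rec.feature_id)
    if rec.label:
        feat.set("label", rec.label)
    type_el = etree.SubElement(feat, "TYPE", id=rec.type_id)
    if rec.type_cv_id:
        type_el.set("cvId", rec.type_cv_id)
    type_el.text = rec.type_id
    method_el = etree.SubElement(feat, "METHOD", id=rec.method_id)
    if rec.method_cv_id:
        method_el.set("cvId", rec.method_cv_id)
    method_el.text = rec.method_id
    etree.SubElement(feat, "START").text = str(rec.start)
    etree.SubElement(feat, "END").text = str(rec.end)
    etree.SubElement(feat, "SCORE").text = (
        "-" if rec.score is None else repr(rec.score))
    etree.SubElement(feat, "ORIENTATION").text = rec.orientation
    etree.SubElement(feat, "PHASE").text = rec.phase
    for note in rec.notes:
        etree.SubElement(feat, "NOTE").text = note
    for href, text in rec.links:
        link = etree.SubElement(feat, "LINK", href=href)
        link.text = text


def render_features(source: SourceDefinition,
                    results: Sequence[FeatureQueryResult],
                    version: str = "1.0") -> DasDocument:
    """FEATURES document: one SEGMENT (or ERRORSEGMENT) per query."""
    root = etree.Element("DASGFF")
    gff = etree.SubElement(root, "GFF")
    for res in results:
        q = res.query
        if not res.segment_known:
            err = etree.SubElement(gff, "ERRORSEGMENT", id=q.segment_id)
            if q.start is not None:
                err.set("start", str(q.start))
                err.set("stop", str(q.stop))
            continue
        start = q.start if q.start is not None else 1
        stop = q.stop if q.stop is not None else (res.segment_stop or 1)
        seg = etree.SubElement(gff, "SEGMENT", id=q.segment_id,
                               start=str(start), stop=str(stop),
                               version=version)
        for rec in res.records:
            _feature_element(seg, rec)
    return DasDocument(command="features", body=root)


def render_sources(definitions: Sequence[SourceDefinition],
                   base_url: str = "") -> DasDocument:
    """SOURCES document listing each source with coordinates and capabilities."""
    root = etree.Element("SOURCES")
    for defn in definitions:
        src_uri = f"{base_url}/{defn.owner}/das/{defn.source_id}"
        source = etree.SubElement(root, "SOURCE", uri=src_uri, title=defn.title)
        if defn.description:
            source.set("description", defn.description)
        maint = etree.SubElement(source, "MAINTAINER")
        if defn.maintainer_email:
            maint.set("email", defn.maintainer_email)
        ver = etree.SubElement(source, "VERSION", uri=src_uri,
                               created=str(defn.created_at))
        cs = defn.coordinate_system
        if cs is not None:
            coords = etree.SubElement(
                ver, "COORDINATES", uri=cs.uri, authority=cs.authority,
                version=cs.version, source=cs.content_type)
            if cs.taxid is not None:
                coords.set("taxid", str(cs.taxid))
            coords.text = f"{cs.authority}_{cs.version},{cs.content_type},{cs.species}"
        for command in ("features", "types", "entry_points"):
            etree.SubElement(
                ver, "CAPABILITY", type=f"das1:{command}",
                query_uri=f"{src_uri}/{command}")
    return DasDocument(command="sources", body=root)


def render_types(source: SourceDefinition,
                 per_segment: Sequence[tuple[Optional[SegmentQuery],
                                             Sequence[tuple[str, Optional[str], int]]]],
                 version: str = "1.0") -> DasDocument:
    """TYPES document; each TYPE element's text content is its count."""
    root = etree.Element("DASTYPES")
    gff = etree.SubElement(root, "GFF")
    for query, aggregates in per_segment:
        seg = etree.SubElement(gff, "SEGMENT", version=version)
        if query is not None:
            seg.set("id", query.segment_id)
            if query.start is not None:
                seg.set("start", str(query.start))
                seg.set("stop", str(query.stop))
        for type_id, cv_id, count in aggregates:
            type_el = etree.SubElement(seg, "TYPE", id=type_id)
            if cv_id:
                type_el.set("cvId", cv_id)
            type_el.text = str(count)
    return DasDocument(command="types", body=root)


def render_entry_points(source: SourceDefinition,
                        extents: Sequence[tuple[str, int, int]],
                        base_url: str = "") -> DasDocument:
    """ENTRY_POINTS document: one SEGMENT per distinct annotated segment."""
    root = etree.Element("DASEP")
    ep = etree.SubElement(
        root, "ENTRY_POINTS",
        href=f"{base_url}/{source.owner}/das/{source.source_id}/entry_points",
        total=str(len(extents)))
    for sid, start, stop in extents:
        etree.SubElement(ep, "SEGMENT", id=sid, start=str(start),
                         stop=str(stop))
    return DasDocument(command="entry_points", body=root)
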