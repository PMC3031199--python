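"""HTTP façade and CLI: per-user DAS URLs plus the source-creation pipeline.

The URL scheme gives every owner namespace its own DAS server:
``/{owner}/das/sources`` lists that owner's sources and
``/{owner}/das/{source_id}/{command}`` serves the DAS commands
(features, types, entry_points) for one source; ``/das/sources`` is the
global listing of publicly listed sources.  One store backs any number
of sources, so new sources appear without restarting the server.

The interactive source-creation wizard is recast as a non-interactive
pipeline driven by a config object: CLI flags override config-file
values, which override metadata directives found in the data file.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional
from urllib.parse import parse_qs
from wsgiref.simple_server import make_server

import click
import yaml

from . import das_protocol, fixtures, mapping as mapping_mod, tabular_ingest
from .das_protocol import (DasDocument, ProtocolError, das_headers,
                           parse_features_params, protocol_error,
                           render_entry_points, render_features,
                           render_sources, render_types)
from .mapping import (DasConcept, FieldMapping, TermStore, apply_mapping,
                      propose_mapping, remember_term, validate_mapping)
from .source_store import (SegmentQuery, SourceDefinition, SourceStore,
                           StoreError, load_coordinate_registry)
from .tabular_ingest import Dialect, SourceFormat, detect_format

logger = logging.getLogger("dasforge.service")

DAS_COMMANDS = ("features", "types", "entry_points")


@dataclass(frozen=True)
class RouteMatch:
    owner: Optional[str]  # None for the global sources listing
    source_id: Optional[str]
    command: str


def route(path: str, mount_prefix: str = "") -> RouteMatch:
    """Resolve a request path to (owner, source_id, command).

    ``/{owner}/das/sources`` -> that owner's listing;
    ``/{owner}/das/{source}/{command}`` -> a DAS command on one source;
    ``/das/sources`` -> the global listing.  Pure function of the path.
    """
    if mount_prefix:
        if not path.startswith(mount_prefix):
            raise ProtocolError("not found", path)
        path = path[len(mount_prefix):]
    parts = [p for p in path.split("/") if p]
    if parts == ["das", "sources"]:
        return RouteMatch(owner=None, source_id=None, command="sources")
    if len(parts) == 3 and parts[1] == "das" and parts[2] == "sources":
        return RouteMatch(owner=parts[0], source_id=None, command="sources")
    if len(parts) == 4 and parts[1] == "das" and parts[3] in DAS_COMMANDS:
        return RouteMatch(owner=parts[0], source_id=parts[2], command=parts[3])
    if len(parts) == 4 and parts[1] == "das":
        raise ProtocolError("bad command", parts[3])
    raise ProtocolError("not found", path)


@dataclass
class PipelineConfig:
    """Everything the creation wizard would have asked, non-interactively."""

    owner: str
    source_id: str
    format: Optional[SourceFormat] = None
    separator: Optional[str] = None
    quote_char: Optional[str] = None
    has_header: Optional[bool] = None
    title: Optional[str] = None
    description: Optional[str] = None
    maintainer_email: Optional[str] = None
    coordinate_system_uri: Optional[str] = None
    listed: bool = True
    #: column name -> DAS concept name, overriding the heuristic proposal
    mapping_overrides: dict[str, str] = field(default_factory=dict)
    #: DAS concept name -> default value (fills empty/"." cells per row)
    defaults: dict[str, str] = field(default_factory=dict)
    #: local type/method identifier -> ontology term accession
    term_associations: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineReport:
    definition: SourceDefinition
    rows_read: int
    features_stored: int
    rows_dropped: int
    row_issues: list[str] = field(default_factory=list)


class PipelineError(Exception):
    """A stage failure; nothing is persisted when this is raised."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"{stage}: {detail}")


def _stage(name: str, fn: Callable, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (tabular_ingest.IngestError, mapping_mod.MappingError,
            StoreError, ValueError) as exc:
        raise PipelineError(name, str(exc)) from exc


def default_term_store() -> TermStore:
    return TermStore.from_table(fixtures.gen_term_table())


def create_source_pipeline(
    lines_or_path: list[str] | str | Path,
    config: PipelineConfig,
    store: SourceStore,
    term_store: Optional[TermStore] = None,
) -> PipelineReport:
    """Run the whole wizard: parse, map, annotate, persist — all or nothing.

    Stage order: format detection, dialect sniffing/parsing, metadata
    directive extraction (pre-populating title/description/maintainer),
    heuristic mapping proposal with config overrides, validation,
    record materialisation, storage.  Any stage error aborts with the
    stage name and leaves the store untouched.
    """
    if isinstance(lines_or_path, (str, Path)):
        lines = tabular_ingest.read_lines(lines_or_path)
    else:
        lines = list(lines_or_path)

    fmt = config.format or _stage("detect_format", detect_format, lines)
    if fmt is SourceFormat.GFF:
        dataset = _stage("parse", tabular_ingest.parse_gff, lines)
    else:
        if config.separator:
            dialect = Dialect(separator=config.separator,
                              quote_char=config.quote_char,
                              has_header=bool(config.has_header))
        else:
            dialect = _stage("sniff_dialect", tabular_ingest.sniff_dialect, lines)
            if config.has_header is not None:
                dialect = Dialect(separator=dialect.separator,
                                  quote_char=config.quote_char or dialect.quote_char,
                                  has_header=config.has_header)
        dataset = _stage("parse", tabular_ingest.parse_delimited, lines, dialect)

    # precedence: config over file directives (directives pre-populate only)
    directives = dataset.directives
    title = config.title or directives.get("source-title") \
        or directives.get("source-name") or config.source_id
    description = config.description or ""
    maintainer = config.maintainer_email \
        or directives.get("source-maintainer", "")

    fmap = _stage("propose_mapping", propose_mapping, dataset)
    if config.mapping_overrides:
        overridden = {col for col in config.mapping_overrides}
        rules = [(col, c) for col, c in fmap.rules if col not in overridden]
        for col, concept_name in config.mapping_overrides.items():
            rules.append((col, DasConcept(concept_name.upper())))
        fmap = FieldMapping(rules=rules, defaults=dict(fmap.defaults))
    for concept_name, value in config.defaults.items():
        fmap.defaults[DasConcept(concept_name.upper())] = value

    issues = validate_mapping(fmap, dataset)
    if issues:
        raise PipelineError("validate_mapping", "; ".join(issues))

    term_store = term_store or default_term_store()
    for local_id, term_id in config.term_associations.items():
        _stage("remember_term", remember_term,
               term_store, config.owner, local_id, term_id)

    records, row_issues = _stage(
        "apply_mapping", apply_mapping, dataset, fmap, term_store,
        source_id=config.source_id, namespace_user=config.owner)

    coordinate_system = None
    if config.coordinate_system_uri:
        registry = load_coordinate_registry(fixtures.gen_coord_registry())
        try:
            coordinate_system = registry[config.coordinate_system_uri]
        except KeyError:
            raise PipelineError("coordinate_system",
                                f"unknown uri {config.coordinate_system_uri!r}")

    definition = SourceDefinition(
        owner=config.owner, source_id=config.source_id, title=title,
        description=description, maintainer_email=maintainer,
        coordinate_system=coordinate_system, listed=config.listed)
    definition = _stage("create_source", store.create_source, definition, records)
    report = PipelineReport(
        definition=definition, rows_read=len(dataset.rows),
        features_stored=len(records),
        rows_dropped=dataset.rows_dropped + len(row_issues),
        row_issues=row_issues)
    logger.info("created %s/%s: %d rows read, %d features stored, %d dropped",
                config.owner, config.source_id, report.rows_read,
                report.features_stored, report.rows_dropped)
    return report


# -- WSGI application ----------------------------------------------------

class DasApplication:
    """WSGI callable serving the DAS protocol for every source in a store."""

    def __init__(self, store: SourceStore, mount_prefix: str = "",
                 base_url: str = ""):
        self.store = store
        self.mount_prefix = mount_prefix
        self.base_url = base_url

    def _dispatch(self, match: RouteMatch,
                  params: dict[str, list[str]]) -> tuple[DasDocument, int]:
        store = self.store
        if match.command == "sources":
            defs = store.list_sources(owner=match.owner)
            return render_sources(defs, base_url=self.base_url), 0
        try:
            source = store.get_source(match.owner, match.source_id)
        except StoreError as exc:
            raise ProtocolError("unknown source", str(exc))
        version = store.source_version(match.owner, match.source_id)
        if match.command == "features":
            queries = parse_features_params(params)
            results = [store.query_features(match.owner, match.source_id, q)
                       for q in queries]
            n = sum(len(r.records) for r in results)
            return render_features(source, results, version=version), n
        if match.command == "types":
            if "segment" in params:
                queries = parse_features_params(params)
                per_segment = [
                    (q, store.aggregate_types(match.owner, match.source_id, q))
                    for q in queries]
            else:
                per_segment = [
                    (None, store.aggregate_types(match.owner, match.source_id))]
            n = sum(c for _, aggs in per_segment for *_x, c in aggs)
            return render_types(source, per_segment, version=version), n
        # entry_points
        extents = store.entry_points(match.owner, match.source_id)
        return render_entry_points(source, extents,
                                   base_url=self.base_url), len(extents)

    def __call__(self, environ, start_response):
        path = environ.get("PATH_INFO", "")
        params = parse_qs(environ.get("QUERY_STRING", ""))
        try:
            match = route(path, self.mount_prefix)
            doc, n = self._dispatch(match, params)
        except ProtocolError as exc:
            status, headers = protocol_error(exc.kind)
            logger.info("%s -> %d (%s)", path, status, exc.kind)
            start_response(f"{status} {exc.kind}",
                           [("Content-Type", "text/plain"),
                            ("X-DAS-Status", exc.kind)]
                           + list(headers.items()))
            return [str(exc).encode()]
        body = doc.to_xml()
        logger.info("%s -> 200 (%d features/items)", path, n)
        start_response("200 OK",
                       [("Content-Type", das_protocol.XML_CONTENT_TYPE),
                        ("Content-Length", str(len(body)))]
                       + list(doc.headers.items()))
        return [body]


def serve(store: SourceStore, host: str = "127.0.0.1", port: int = 8080,
          mount_prefix: str = "") -> None:
    app = DasApplication(store, mount_prefix=mount_prefix,
                         base_url=f"http://{host}:{port}{mount_prefix}")
    httpd = make_server(host, port, app)
    logger.info("serving DAS on http://%s:%d%s", host, port, mount_prefix)
    httpd.serve_forever()


# -- CLI -----------------------------------------------------------------

def _parse_kv(pairs: tuple[str, ...], what: str) -> dict[str, str]:
    out = {}
    for pair in pairs:
        key, sep, value = pair.partition("=")
        if not sep:
            raise click.BadParameter(f"{what} must be KEY=VALUE, got {pair!r}")
        out[key] = value
    return out


@click.group()
@click.option("--store", "store_path", default="dasforge.sqlite",
              show_default=True, help="Path to the source database.")
@click.option("-v", "--verbose", is_flag=True, help="Debug logging.")
@click.pass_context
def cli(ctx, store_path, verbose):
    """Create, manage and serve DAS 1.6 annotation sources."""
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    ctx.obj = SourceStore(store_path)


@cli.command()
@click.option("--input", "input_path", required=True,
              type=click.Path(exists=True, dir_okay=False))
@click.option("--owner", required=True)
@click.option("--source-id", required=True)
@click.option("--config", "config_path", type=click.Path(exists=True),
              help="YAML config with pipeline options (flags override it).")
@click.option("--format", "fmt", type=click.Choice(["gff", "csv"]))
@click.option("--separator")
@click.option("--title")
@click.option("--description")
@click.option("--maintainer")
@click.option("--coords", help="Coordinate-system URI from the registry.")
@click.option("--map", "map_", multiple=True, metavar="COL=CONCEPT")
@click.option("--default", "default_", multiple=True, metavar="CONCEPT=VALUE")
@click.option("--term", "term_", multiple=True, metavar="ID=TERM")
@click.option("--unlisted", is_flag=True)
@click.pass_obj
def create(store, input_path, owner, source_id, config_path, fmt, separator,
           title, description, maintainer, coords, map_, default_, term_,
           unlisted):
    """Create a DAS source from an annotation file."""
    overrides = dict(
        owner=owner, source_id=source_id,
        format=SourceFormat.GFF if fmt == "gff"
        else SourceFormat.DELIMITED if fmt == "csv" else None,
        separator=separator, title=title, description=description,
        maintainer_email=maintainer, coordinate_system_uri=coords,
        mapping_overrides=_parse_kv(map_, "--map") or None,
        defaults=_parse_kv(default_, "--default") or None,
        term_associations=_parse_kv(term_, "--term") or None,
    )
    if config_path:
        config = PipelineConfig.from_yaml(config_path, **overrides)
    else:
        config = PipelineConfig(
            **{k: v for k, v in overrides.items() if v is not None})
    if unlisted:
        config.listed = False
    try:
        report = create_source_pipeline(input_path, config, store)
    except PipelineError as exc:
        raise click.ClickException(str(exc))
    click.echo(f"created {owner}/{source_id}: {report.rows_read} rows read, "
               f"{report.features_stored} features stored, "
               f"{report.rows_dropped} rows dropped")


@cli.command(name="list")
@click.option("--owner")
@click.pass_obj
def list_cmd(store, owner):
    """List sources (all public ones, or everything owned by --owner)."""
    for defn in store.list_sources(owner=owner):
        flag = "" if defn.listed else " (unlisted)"
        click.echo(f"{defn.owner}/das/{defn.source_id}\t{defn.title}{flag}")


@cli.command()
@click.option("--owner", required=True)
@click.option("--source-id", required=True)
@click.pass_obj
def delete(store, owner, source_id):
    """Delete a source (drops its six tables)."""
    try:
        store.delete_source(owner, source_id)
    except StoreError as exc:
        raise click.ClickException(str(exc))
    click.echo(f"deleted {owner}/{source_id}")


@cli.command(name="serve")
@click.option("--host", default="127.0.0.1", show_default=True)
@click.option("--port", default=8080, show_default=True)
@click.option("--mount-prefix", default="", show_default=True)
@click.pass_obj
def serve_cmd(store, host, port, mount_prefix):
    """Serve every stored source over the DAS protocol."""
    serve(store, host=host, port=port, mount_prefix=mount_prefix)
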