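# dasforge

`dasforge` turns plain annotation files — GFF or delimiter-separated
tables — into fully functional, queryable **DAS 1.6** annotation sources.
It is aimed at researchers who have sequence annotations in a file (gene
calls, predicted features, analysis results tied to chromosome or protein
coordinates) and want them served over the Distributed Annotation System
so that DAS clients such as genome browsers can overlay them on reference
sequences, without writing a server or a data-access layer.

The Distributed Annotation System is a REST+XML protocol that federates
biological sequence annotations: *annotation servers* publish positioned
features (each with a segment id, 1-based inclusive `start`/`end`, a
`type` and a `method`, optionally annotated with controlled-vocabulary
accessions via the DAS 1.6 `cvId` attribute), while *reference servers*
such as Ensembl or UniProt provide the sequences themselves. A source is
identified by species and assembly through its *coordinate system* (for
example `GRCh37` / *Homo sapiens*).

## What the toolkit does

The pipeline mirrors a source-creation wizard, run non-interactively:

1. **Ingest** (`tabular_ingest`) — detects whether the file is GFF
   (≥90% of data lines split on tab into 8–9 fields with integer
   coordinates) or delimited text; for delimited files it sniffs the
   separator among comma, semicolon and tab (lowest per-line count
   variance outside quotes; ties broken tab > comma > semicolon) and
   detects a header row. `##key value` metadata directives
   (`source-name`, `source-title`, `source-maintainer`) pre-populate the
   source metadata.
2. **Mapping** (`mapping`) — links file columns to DAS concepts
   (SEGMENT_ID, START, END, TYPE, METHOD, SCORE, ...), either from the
   fixed canonical GFF layout or by name-pattern heuristics
   (`chromosome` → SEGMENT_ID, `stop` → END, ...). Per-row defaults fill
   concepts whose cells are empty or the GFF null `"."`, and ontology
   terms remembered per user and local identifier attach `cvId`
   accessions to types and methods.
3. **Storage** (`source_store`) — each source lives in its own six
   SQLite tables (`meta`, `segments`, `types`, `methods`, `features`,
   `annexes`); no table is shared, so deleting a source is a set of
   whole-table drops and sources cannot interfere. Interval queries use
   the DAS overlap rule `feature.start ≤ stop ∧ feature.end ≥ start` on
   1-based inclusive coordinates.
4. **Protocol** (`das_protocol`) — renders the DAS 1.6 `sources`,
   `features`, `types` and `entry_points` XML documents with
   `X-DAS-Version: DAS/1.6` on every response, `ERRORSEGMENT` for
   unknown segments, and `cvId` attributes wherever terms are known.
5. **Serving** (`das_service`) — routes the per-owner URL scheme
   `/{owner}/das/sources` and `/{owner}/das/{source}/{command}` over a
   WSGI app, so one server exposes every stored source ("hydra"-style)
   without restarts.

`fixtures` generates every input deterministically (GFF, CSV in any
dialect, an ontology-term table spanning SO/Biosapiens/PSI-MOD/ECO, a
coordinate-system registry including GRCh37 / *Homo sapiens*), so the
whole package builds and tests offline.

## Worked example

Create a 50-feature GFF file with embedded metadata directives, publish
it as a source owned by `john`, and inspect it:

```sh
python - <<'EOF'
from dasforge import fixtures
open("demo.gff", "w").write(fixtures.gen_gff(
    50, seed=1, directives={"source-title": "Demo annotations",
                            "source-maintainer": "jane@example.org"}))
EOF

dasforge --store demo.sqlite create --input demo.gff \
    --owner john --source-id dataset1 \
    --coords http://www.dasregistry.org/coordsys/CS_DS40 \
    --term gene=SO:0000704
dasforge --store demo.sqlite list
```

prints

```
created john/dataset1: 50 rows read, 50 features stored, 0 rows dropped
john/das/dataset1	Demo annotations
```

meaning all 50 GFF lines parsed, mapped and stored (none dropped), the
title came from the file's `##source-title` directive, and every `gene`
feature now carries `cvId="SO:0000704"`. `dasforge --store demo.sqlite
serve --port 8080` then answers standard DAS requests, e.g.

```
http://127.0.0.1:8080/john/das/dataset1/features?segment=chr1:1,1000000
http://127.0.0.1:8080/john/das/sources
```

The same pipeline is available as a library call
(`dasforge.create_source_pipeline`) driven by a `PipelineConfig` or a
YAML config file; CLI flags override config values, which override the
file's directives.

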