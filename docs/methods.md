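# Methods

## The problem and the model

DAS (the Distributed Annotation System) federates biological sequence
annotations: a source exposes positioned features over HTTP as XML, and
clients overlay them on reference sequences. A feature is a tuple
(segment id, start, end, type, method) with optional score, orientation
(`+`/`-`/`0`), phase (`0`/`1`/`2`/`-`), label, notes and links; all
coordinates are **1-based inclusive**, and DAS 1.6 adds a `cvId`
attribute carrying a controlled-vocabulary accession for the type and
the method. `dasforge` converts user files into such sources and serves
the four annotation commands (`sources`, `features`, `types`,
`entry_points`). Alignment/3D-structure DAS commands, stylesheets,
writeback and sequence serving are out of scope: this is an
annotation-only server, and reference servers provide the sequences.

## Ingestion

**Format detection.** A file is classified GFF when at least 90% of its
non-comment lines split on tab into exactly 8 or 9 fields with
integer-like columns 4 and 5; everything else is treated as delimited
text. The 90% threshold tolerates the odd malformed line without
misclassifying genuinely tabular data.

**GFF.** The 9-column layout common to GFF2 and GFF3 is accepted;
attributes parse as `key=value;` (GFF3) with a `key value;` (GFF2)
fallback, preferring `=` when present — this maximises accepted inputs
without a version flag. The `.` null token is preserved verbatim by the
parser and interpreted only at mapping time. Lines with non-integer
coordinates are dropped with a per-line warning rather than failing the
file.

**Dialect sniffing.** Only comma, semicolon and tab are ever proposed.
A candidate is eligible when it occurs at least once (outside double
quotes) on every data line; among eligible candidates the one with the
lowest population variance of per-line counts wins, with ties broken by
the fixed precedence tab > comma > semicolon. The statistic is
deterministic and cheap, and the precedence makes mixed-punctuation
lines resolve reproducibly. A header is assumed when the first data row
is non-numeric at every position where some later row is numeric; an
explicit dialect always overrides the sniffer.

**Permissiveness.** Ragged rows are padded to the modal width (with a
warning) rather than rejected; undecodable bytes are replaced under
UTF-8 with a warning. `##key value` directives are collected with
lower-cased keys, later duplicates overriding earlier ones; unknown
keys are retained with a warning so user metadata is never silently
discarded.

## Mapping

The concept set is closed: SEGMENT_ID, START, END (the required trio),
TYPE, METHOD, SCORE, ORIENTATION, PHASE, FEATURE_ID, LABEL, NOTE, LINK.
Multiplicities: START and END accept at most one rule each; NOTE
aggregates every mapped column as `"column: value"` strings; all other
concepts take the first non-empty mapped cell in rule order. This merge
rule keeps one-to-many and many-to-many mappings deterministic.

Defaults fill a concept **per row**, only when the row's mapped cells
are empty or `"."` (`absent_only`); there is no override mode. Strand
`.` maps to orientation `0` (DAS's "not stranded"). A missing feature
id is synthesised as `<source_id>_f<row_number>`, which is unique and
reproducible; a duplicate id in the input is suffixed with the row
number and logged rather than dropped.

The heuristic proposal maps GFF columns to the canonical layout (seqid →
SEGMENT_ID, source → METHOD, attributes `ID` → FEATURE_ID, ...); for
delimited files, case-insensitive full-name patterns are tried in a
fixed order (`chrom|chromosome|seq.?id|seqname|segment`,
`start|begin|from`, `end|stop|to`, `type|feature`, `method|source`,
`score|value`, `strand|orientation`, `phase|frame`, `id|name`, `label`).
A single-valued concept is proposed at most once; unmatched columns
become NOTE so no data is silently lost. The pattern table is a module
constant and easy to extend.

**Ontology terms.** Term selection is a lookup against a packaged
vocabulary table (accession, name, ontology) covering small curated
subsets of the Sequence Ontology, Biosapiens, PSI-MOD and the Evidence
Code Ontology; live ontology services are deliberately not contacted.
Associations are keyed by (owner namespace, local identifier), last
write wins, so a user's previous choice for e.g. `gene` is re-applied
automatically in later sources.

## Storage

Each source owns exactly six SQLite tables,
`<owner>__<source_id>__{meta, segments, types, methods, features,
annexes}`. The split keeps one table per entity kind (notes and links
share `annexes`), so creating a source writes each table once, no two
sources ever write the same table, and deletion is six `DROP TABLE`
statements. There is **no central catalog**: sources are discovered by
scanning `sqlite_master` for `*__meta` tables and reading owner and
source id from the meta contents, which keeps the
six-tables-per-source census exact and avoids any name-parsing
ambiguity from underscores in identifiers. The backend is a single
embedded database file (or `:memory:`); multi-server sharding and
concurrent multi-writer use are non-goals.

Coordinates are stored 1-based inclusive end to end — GFF and DAS agree
on this convention, so no conversion layer exists anywhere. Interval
queries use `start ≤ query.stop AND end ≥ query.start`, ordered by
(start, end, feature_id); an unknown segment returns an empty result
carrying a `segment_known=False` flag, distinct from a known segment
with no overlap, so the protocol layer can emit `ERRORSEGMENT` instead
of an empty `SEGMENT`. Anonymous/temporary sources are supported by an
optional `expires_at` honoured by the global listing (off by default;
no expiry duration is imposed).

## Protocol

Documents are rendered with lxml and validated structurally (required
roots `DASGFF`/`SOURCES`/`DASTYPES`/`DASEP`, required children and
attributes, re-parse checks) rather than against the normative DTDs,
which are external artifacts. Every response — including errors —
carries `X-DAS-Version: DAS/1.6` and an `X-DAS-Capabilities` header
listing the implemented commands only. Error mapping: unknown source or
unroutable path → 404, unknown command or malformed arguments → 400.
The segment `version` attribute is an opaque content hash of the
source's records, since sequence versioning is not modelled. A missing
score renders as `-`; XML escaping is delegated to the serializer and
fuzz-tested with quotes, ampersands and angle brackets.

## Service

The URL scheme gives each owner a DAS server of their own:
`/{owner}/das/sources` and `/{owner}/das/{source}/{command}`, plus the
global `/das/sources` listing of publicly listed sources. Routing is a
pure function of the path. The wizard is recast as a config-driven
pipeline with fixed precedence **flags > config file > file
directives**; any stage failure aborts with the stage name before
anything is persisted (storage creation is a single transaction).
Authentication is out of scope: the owner is a trusted namespace
argument. The server is a stdlib WSGI application behind `wsgiref`,
logging one line per request (path, status, item count) to stderr —
adequate for the single-writer, low-traffic deployments the design
targets.

## Synthetic data

The generators are pure functions of their arguments including the
seed. `gen_gff` draws intervals uniformly on [1, 10⁶] with start ≤ end,
types from {gene, exon, repeat_region}, strands from {+, -, .}, a 20%
chance of a null score, and per-feature `ID=` attributes; directives and
comment lines are injectable. `gen_csv` uses heuristically mappable
header names (chromosome, start, end, type, score, strand) and honours
the declared separator, quoting and header flag. Generated cells never
contain an unquoted candidate separator, so dialect recovery on the
generated suite is a test of the sniffer, not of quoting corner cases;
real-world files with exotic quoting, multi-character separators or
embedded newlines are outside what these fixtures exercise, and passing
tests show correctness of the mechanism, not robustness to arbitrarily
dirty data. The ontology and coordinate-registry fixtures are tiny
curated subsets with realistic accession syntax, not real releases.

## Problem sizes and numerics

The test suite and the acceptance script use desk-scale sizes chosen to
exercise every code path quickly: 50-feature sources for round trips,
a 60-file sniffing suite (3 separators × quoting × header × 5 seeds),
500 stored features against 1,000 randomised interval queries compared
with an independent brute-force scan, and 20-step random
create/replace/delete lifecycles. Scores round-trip through `repr` so
float equality is exact; all randomness is seeded.

## Known limitations

Excel/ODS binaries, BED/VCF/GTF-specific dialects, hierarchical feature
linkage (TARGET/PARENT), stylesheets, maxbins, sequence/alignment/
structure commands, DAS registry auto-registration and any web UI are
not implemented. The heuristic pattern table is a reconstruction and
will not match every column-naming convention; unmatched columns fall
back to NOTE rather than being guessed.
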