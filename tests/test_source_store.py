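"""Per-source table isolation, lifecycle, and interval-query correctness."""

import random

import pytest

from dasforge import (AnnotationRecord, CoordinateSystem, SegmentQuery,
                      SourceDefinition, SourceStore, StoreError, fixtures,
                      load_coordinate_registry)


def make_records(n, segments=("chr1", "chr2"), seed=0, types=("gene", "exon")):
    rng = random.Random(seed)
    out = []
    for i in range(1, n + 1):
        a, b = rng.randint(1, 10_000), rng.randint(1, 10_000)
        out.append(AnnotationRecord(
            segment_id=rng.choice(list(segments)),
            start=min(a, b), end=max(a, b),
            type_id=rng.choice(list(types)), method_id="sim",
            feature_id=f"f{i}"))
    return out


def brute_force(records, query):
    """Independent linear scan implementing the DAS overlap semantics."""
    hits = []
    for r in records:
        if r.segment_id != query.segment_id:
            continue
        if query.start is not None and not (
                r.start <= query.stop and r.end >= query.start):
            continue
        if query.type_filter is not None and query.type_filter not in (
                r.type_id, r.type_cv_id):
            continue
        hits.append(r)
    return sorted(hits, key=lambda r: (r.start, r.end, r.feature_id))


def defn(owner="o", source_id="s", **kw):
    return SourceDefinition(owner=owner, source_id=source_id, **kw)


class TestLifecycle:
    def test_create_makes_six_tables_and_segment_summary(self, store):
        records = make_records(10, seed=1)
        store.create_source(defn(), records)
        assert store.table_census() == 6
        segs = store.entry_points("o", "s")
        assert len(segs) == len({r.segment_id for r in records})

    def test_duplicate_create_rejected(self, store):
        store.create_source(defn(), make_records(3))
        with pytest.raises(StoreError, match="source exists"):
            store.create_source(defn(), make_records(3))

    def test_create_with_no_records_rejected(self, store):
        with pytest.raises(StoreError, match="no valid features"):
            store.create_source(defn(), [])

    def test_delete_leaves_other_sources_untouched(self, store):
        store.create_source(defn(source_id="a"), make_records(5, seed=1))
        store.create_source(defn(source_id="b"), make_records(7, seed=2))
        before = sum(len(store.query_features("o", "b", SegmentQuery(s)).records)
                     for s in ("chr1", "chr2"))
        store.delete_source("o", "a")
        after = sum(len(store.query_features("o", "b", SegmentQuery(s)).records)
                    for s in ("chr1", "chr2"))
        assert before == after == 7
        assert store.table_census() == 6

    def test_delete_unknown_source_is_an_error(self, store):
        with pytest.raises(StoreError, match="unknown source"):
            store.delete_source("o", "nope")

    def test_source_id_reusable_after_delete(self, store):
        store.create_source(defn(), make_records(3))
        store.delete_source("o", "s")
        store.create_source(defn(), make_records(4))
        assert store.table_census() == 6

    def test_replace_rewrites_data_but_keeps_meta(self, store):
        store.create_source(defn(title="Kept"), make_records(5))
        store.replace_source_data("o", "s", make_records(3, seed=9))
        assert store.get_source("o", "s").title == "Kept"
        n = sum(len(store.query_features("o", "s", SegmentQuery(s)).records)
                for s in ("chr1", "chr2"))
        assert n == 3

    def test_replace_with_nothing_keeps_old_data(self, store):
        store.create_source(defn(), make_records(5))
        with pytest.raises(StoreError):
            store.replace_source_data("o", "s", [])
        n = sum(len(store.query_features("o", "s", SegmentQuery(s)).records)
                for s in ("chr1", "chr2"))
        assert n == 5

    def test_census_is_six_per_source_through_random_lifecycle(self, store):
        rng = random.Random(42)
        live = set()
        for step in range(20):
            op = rng.choice(["create", "delete", "replace"])
            if op == "create" or not live:
                sid = f"s{step}"
                store.create_source(defn(source_id=sid),
                                    make_records(4, seed=step))
                live.add(sid)
            elif op == "delete":
                sid = rng.choice(sorted(live))
                store.delete_source("o", sid)
                live.discard(sid)
            else:
                sid = rng.choice(sorted(live))
                store.replace_source_data("o", sid,
                                          make_records(3, seed=100 + step))
            assert store.table_census() == 6 * len(live)

    def test_invalid_identifiers_rejected(self):
        with pytest.raises(StoreError, match="source_id"):
            SourceDefinition(owner="ok", source_id="bad/slash")


class TestListing:
    def test_unlisted_source_hidden_globally_visible_to_owner(self, store):
        store.create_source(defn(owner="u", source_id="hidden", listed=False),
                            make_records(2))
        assert store.list_sources() == []
        assert [d.source_id for d in store.list_sources(owner="u")] == ["hidden"]

    def test_empty_store_lists_nothing(self, store):
        assert store.list_sources() == []

    def test_expired_source_dropped_from_global_listing(self, store):
        store.create_source(defn(expires_at=100.0), make_records(2))
        assert store.list_sources(now=200.0) == []
        assert len(store.list_sources(owner="o", now=200.0)) == 1

    def test_coordinate_system_round_trips_through_meta(self, store):
        registry = load_coordinate_registry(fixtures.gen_coord_registry())
        grch37 = next(cs for cs in registry.values() if cs.authority == "GRCh")
        store.create_source(defn(coordinate_system=grch37), make_records(2))
        got = store.get_source("o", "s").coordinate_system
        assert got == grch37
        assert got.species == "Homo sapiens" and got.version == "37"


class TestQueries:
    def test_range_overlap_is_inclusive(self, store):
        records = [
            AnnotationRecord(segment_id="chr1", start=100, end=200,
                             type_id="gene", method_id="m", feature_id="a"),
            AnnotationRecord(segment_id="chr1", start=300, end=400,
                             type_id="gene", method_id="m", feature_id="b"),
        ]
        store.create_source(defn(), records)
        hit = store.query_features("o", "s", SegmentQuery("chr1", 150, 250))
        assert [r.feature_id for r in hit.records] == ["a"]
        gap = store.query_features("o", "s", SegmentQuery("chr1", 201, 299))
        assert gap.records == [] and gap.segment_known

    def test_unknown_segment_flagged_distinctly(self, store):
        store.create_source(defn(), make_records(3))
        res = store.query_features("o", "s", SegmentQuery("chrZ", 1, 10))
        assert res.records == [] and not res.segment_known

    def test_unknown_source_raises(self, store):
        with pytest.raises(StoreError):
            store.query_features("o", "nope", SegmentQuery("chr1"))

    def test_query_matches_brute_force_oracle(self, store):
        records = make_records(500, segments=("chr1", "chr2", "chr3"), seed=7)
        store.create_source(defn(), records)
        rng = random.Random(11)
        for _ in range(300):
            seg = rng.choice(["chr1", "chr2", "chr3", "chrZ"])
            if rng.random() < 0.8:
                a, b = rng.randint(1, 10_000), rng.randint(1, 10_000)
                q = SegmentQuery(seg, min(a, b), max(a, b),
                                 type_filter=rng.choice([None, "gene", "exon"]))
            else:
                q = SegmentQuery(seg,
                                 type_filter=rng.choice([None, "gene"]))
            got = store.query_features("o", "s", q)
            expected = brute_force(records, q)
            assert [r.feature_id for r in got.records] == \
                   [r.feature_id for r in expected]
            assert got.segment_known == (seg != "chrZ")

    def test_aggregate_types_counts_match_feature_totals(self, store):
        records = make_records(60, seed=13)
        store.create_source(defn(), records)
        q = SegmentQuery("chr1", 1, 5000)
        aggs = store.aggregate_types("o", "s", q)
        assert sum(c for *_x, c in aggs) == len(brute_force(records, q))
        full = store.aggregate_types("o", "s")
        assert sum(c for *_x, c in full) == len(records)

    def test_aggregate_types_empty_range(self, store):
        store.create_source(defn(), [
            AnnotationRecord(segment_id="chr1", start=10, end=20,
                             type_id="gene", method_id="m", feature_id="a")])
        assert store.aggregate_types("o", "s",
                                     SegmentQuery("chr1", 500, 600)) == []

    def test_entry_points_report_max_end_per_segment(self, store):
        store.create_source(defn(), [
            AnnotationRecord(segment_id="chr1", start=5, end=9,
                             type_id="gene", method_id="m", feature_id="a"),
            AnnotationRecord(segment_id="chr1", start=100, end=400,
                             type_id="gene", method_id="m", feature_id="b"),
            AnnotationRecord(segment_id="chr2", start=1, end=50,
                             type_id="gene", method_id="m", feature_id="c")])
        assert store.entry_points("o", "s") == [
            ("chr1", 1, 400), ("chr2", 1, 50)]

    def test_invalid_query_ranges_rejected(self):
        with pytest.raises(StoreError):
            SegmentQuery("chr1", 10, None)
        with pytest.raises(StoreError):
            SegmentQuery("chr1", 10, 5)

    def test_notes_and_links_round_trip_through_annexes(self, store):
        rec = AnnotationRecord(
            segment_id="chr1", start=1, end=9, type_id="gene",
            method_id="m", feature_id="a",
            notes=["note one", "note two"],
            links=[("http://x.org/a", "link a")])
        store.create_source(defn(), [rec])
        got = store.query_features("o", "s", SegmentQuery("chr1")).records[0]
        assert got.notes == rec.notes and got.links == rec.links


def test_coordinate_registry_includes_grch37_human():
    registry = load_coordinate_registry(fixtures.gen_coord_registry())
    assert any(cs.authority == "GRCh" and cs.version == "37"
               and cs.species == "Homo sapiens" and cs.taxid == 9606
               for cs in registry.values())
    assert len(registry) >= 3


def test_species_required_with_taxid():
    with pytest.raises(StoreError):
        CoordinateSystem(uri="u", authority="A", version="1",
                         species="", taxid=9606)
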