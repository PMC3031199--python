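import pytest
from lxml import etree

from dasforge import (DasApplication, PipelineConfig, SourceStore, TermStore,
                      create_source_pipeline, fixtures)


@pytest.fixture
def store():
    s = SourceStore(":memory:")
    yield s
    s.close()


@pytest.fixture
def term_store():
    return TermStore.from_table(fixtures.gen_term_table())


@pytest.fixture
def john_dataset1(store):
    """A 50-feature GFF source owned by john, as in the published URL example."""
    gff = fixtures.gen_gff(50, seed=1)
    config = PipelineConfig(
        owner="john", source_id="dataset1",
        maintainer_email="john@example.org",
        coordinate_system_uri="http://www.dasregistry.org/coordsys/CS_DS40")
    report = create_source_pipeline(gff.splitlines(), config, store)
    return report


@pytest.fixture
def wsgi_get(store):
    """GET against the DAS WSGI app; returns (status_code, headers, body)."""
    app = DasApplication(store)

    def get(path, query_string=""):
        captured = {}

        def start_response(status, headers):
            captured["status"] = int(status.split(" ", 1)[0])
            captured["headers"] = dict(headers)

        body = b"".join(app({"PATH_INFO": path,
                             "QUERY_STRING": query_string}, start_response))
        return captured["status"], captured["headers"], body

    return get


def parse_xml(body: bytes) -> etree._Element:
    return etree.fromstring(body)
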