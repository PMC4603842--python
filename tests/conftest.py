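import pytest

from nanopubkit.config import RunConfig
from nanopubkit.context_graphs import EntityLink, ProvenanceContext, PublicationMeta
from nanopubkit.rdf_core import Iri
from nanopubkit.synthetic_data import build_store, table2_fixture
from nanopubkit.templates import default_vocabulary


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def policy(config):
    return config.policy


@pytest.fixture(scope="session")
def vocab(config):
    return default_vocabulary(config)


@pytest.fixture()
def prov_ctx():
    return ProvenanceContext(
        workflow_activity_iri=Iri("https://example.org/workflow/run/1"),
        research_object_iri=Iri("https://example.org/ro/pack"),
        inputs=(
            EntityLink(Iri("https://example.org/data/in1"), Iri("https://example.org/ro/pack/in1"), "expression"),
            EntityLink(Iri("https://example.org/data/in2"), Iri("https://example.org/ro/pack/in2"), "cpg-track"),
        ),
        outputs=(
            EntityLink(Iri("https://example.org/data/out1"), Iri("https://example.org/ro/pack/out1"), "result"),
        ),
        agent_iri=Iri("https://orcid.org/0000-0002-0000-0001"),
        execution_time="2015-02-09T12:00:00+00:00",
    )


@pytest.fixture()
def pub_meta():
    return PublicationMeta(
        authors=(Iri("https://orcid.org/0000-0002-0000-0001"),
                 Iri("https://orcid.org/0000-0002-0000-0002")),
        created="2015-02-09T00:00:00+00:00",
        license_iri=Iri("https://creativecommons.org/licenses/by/4.0/"),
    )


@pytest.fixture(scope="session")
def table2_bundle():
    return table2_fixture()


@pytest.fixture(scope="session")
def table2_store(table2_bundle):
    store, corpus = build_store(table2_bundle)
    return store


@pytest.fixture(scope="session")
def table2_corpus(table2_bundle):
    store, corpus = build_store(table2_bundle)
    return corpus
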