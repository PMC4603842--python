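"""Quad model, IRI minting, CURIE resolution and serialization round trips."""

import hashlib
import random

import pytest
from hypothesis import given, settings, strategies as st

from nanopubkit.config import DEFAULT_PREFIXES
from nanopubkit.errors import InvalidArgumentError, ParseError, ResolutionError
from nanopubkit.rdf_core import (
    GraphBundle,
    Iri,
    LiteralValue,
    Quad,
    UriPolicy,
    mint_iri,
    read_quads,
    resolve_curie,
    write_quads,
)

POLICY = UriPolicy(base_namespace=Iri("https://example.org/np/"))


class TestTerms:
    @pytest.mark.parametrize("bad", ["", "no-scheme", "http://a b", "rel/path", "x:"])
    def test_rejects_non_absolute_iris(self, bad):
        with pytest.raises(InvalidArgumentError):
            Iri(bad)

    def test_literal_datatype_language_mutually_exclusive(self):
        with pytest.raises(InvalidArgumentError):
            LiteralValue("x", datatype=Iri("http://www.w3.org/2001/XMLSchema#int"), language="en")

    def test_xsd_string_datatype_is_normalized_away(self):
        a = LiteralValue("x", datatype=Iri("http://www.w3.org/2001/XMLSchema#string"))
        assert a == LiteralValue("x")


class TestMinting:
    def test_slug_concatenation(self):
        assert mint_iri(POLICY, "nanopub", "degene-3064").value == "https://example.org/np/degene-3064"

    def test_idempotent(self):
        assert mint_iri(POLICY, "promoter", "25-pr1") == mint_iri(POLICY, "promoter", "25-pr1")

    def test_content_hash_suffix_matches_independent_digest(self):
        policy = UriPolicy(base_namespace=Iri("https://example.org/np/"), strategy="content-hash")
        minted = mint_iri(policy, "nanopub", "degene-3064")
        digest = hashlib.sha256(b"degene-3064").hexdigest()  # independent recomputation
        assert minted.value.endswith(digest)

    def test_graph_parts_are_fragments_of_the_nanopub_iri(self):
        np_iri = mint_iri(POLICY, "nanopub", "degene-25")
        for part in ("head", "assertion", "provenance", "pubinfo"):
            assert mint_iri(POLICY, part, "degene-25").value == f"{np_iri.value}#{part}"

    def test_empty_key_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mint_iri(POLICY, "nanopub", "")

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mint_iri(POLICY, "gene", "25")

    @pytest.mark.parametrize("strategy", ["slug", "content-hash"])
    def test_injective_over_randomized_kind_key_pairs(self, strategy):
        policy = UriPolicy(base_namespace=Iri("https://example.org/np/"), strategy=strategy)
        rng = random.Random(0)
        kinds = ["nanopub", "association", "promoter", "region", "entity"]
        pairs = {
            (rng.choice(kinds), "".join(rng.choices("abc/:-_%0 1", k=rng.randint(1, 12))))
            for _ in range(10_000)
        }
        minted = {mint_iri(policy, k, key).value for k, key in pairs}
        assert len(minted) == len(pairs)


class TestCurie:
    @pytest.mark.parametrize(
        "curie,expected",
        [
            ("so:SO_0001411", "http://purl.obolibrary.org/obo/SO_0001411"),
            ("so:SO_0000733", "http://purl.obolibrary.org/obo/SO_0000733"),
            ("geneid:25", "http://bio2rdf.org/geneid:25"),
        ],
    )
    def test_resolves_against_default_prefixes(self, curie, expected):
        assert resolve_curie(curie, DEFAULT_PREFIXES).value == expected

    def test_unknown_prefix_is_a_resolution_error(self):
        with pytest.raises(ResolutionError):
            resolve_curie("x:y", {})


def quad_strategy():
    iri = st.sampled_from(
        [Iri(f"https://example.org/r/{i}") for i in range(12)]
        + [Iri("http://bio2rdf.org/geneid:25")]
    )
    literal = st.one_of(
        st.text(
            alphabet=st.characters(codec="utf-8", exclude_categories=("Cs", "Cc")),
            max_size=12,
        ).map(LiteralValue),
        st.text(alphabet="abc ", max_size=8).map(lambda s: LiteralValue(s, language="en")),
        st.integers(0, 99).map(
            lambda i: LiteralValue(str(i), datatype=Iri("http://www.w3.org/2001/XMLSchema#integer"))
        ),
    )
    graph = st.sampled_from([Iri(f"https://example.org/g/{i}") for i in range(3)])
    return st.builds(Quad, subject=iri, predicate=iri, object=st.one_of(iri, literal), graph=graph)


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["trig", "nquads"])
    def test_empty_bundle_serializes_to_empty_document(self, dialect):
        text = write_quads(GraphBundle(), dialect)
        assert read_quads(text, dialect) == GraphBundle()

    @pytest.mark.parametrize("dialect", ["trig", "nquads"])
    def test_single_quad_survives(self, dialect):
        b = GraphBundle(
            [
                Quad(
                    Iri("https://example.org/s"),
                    Iri("https://example.org/p"),
                    LiteralValue("autophagy", language="en"),
                    Iri("https://example.org/g"),
                )
            ]
        )
        again = read_quads(write_quads(b, dialect), dialect)
        assert again == b and len(again) == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(quads=st.sets(quad_strategy(), max_size=25))
    def test_generated_bundles_round_trip_in_both_dialects(self, quads):
        b = GraphBundle(quads)
        for dialect in ("trig", "nquads"):
            assert read_quads(write_quads(b, dialect), dialect) == b

    def test_nquads_output_is_line_sorted(self):
        rng = random.Random(1)
        quads = [
            Quad(
                Iri(f"https://example.org/s/{rng.randint(0, 99)}"),
                Iri("https://example.org/p"),
                Iri(f"https://example.org/o/{i}"),
                Iri("https://example.org/g"),
            )
            for i in range(20)
        ]
        lines = write_quads(GraphBundle(quads), "nquads").splitlines()
        assert lines == sorted(lines)

    def test_no_blank_node_labels_in_output(self, table2_corpus):
        for dialect in ("trig", "nquads"):
            text = write_quads(table2_corpus[0].bundle(), dialect)
            assert "_:" not in text

    def test_parse_error_carries_line_number(self):
        with pytest.raises(ParseError) as exc:
            read_quads("<https://a.org/s> <https://a.org/p> .\nbroken line here", "nquads")
        assert exc.value.line is not None

    def test_turtle_read_homes_triples_into_named_graph(self):
        b = read_quads(
            "@prefix ex: <https://example.org/> . ex:s ex:p ex:o .",
            "turtle",
            graph_iri=Iri("urn:x-test:g"),
        )
        assert b.graph_iris() == {Iri("urn:x-test:g")}
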