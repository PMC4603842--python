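"""Nanopublication assembly, validation, and document round trips."""

import random

import pytest

from nanopubkit.assembler import (
    Nanopublication,
    assemble,
    build_corpus,
    build_nanopub,
    read_corpus,
    read_nanopub,
    validate,
    write_corpus,
    write_nanopub,
)
from nanopubkit.config import NP_HAS_ASSERTION
from nanopubkit.context_graphs import build_provenance_graph, build_pubinfo_graph
from nanopubkit.errors import AssemblyError, StructureError
from nanopubkit.rdf_core import GraphBundle, Iri, mint_iri, write_quads
from nanopubkit.templates import DEGeneRecord, OverlapRecord, build_de_assertion


@pytest.fixture()
def one_np(vocab, policy, prov_ctx, pub_meta):
    return build_nanopub(DEGeneRecord(25, "ABL1"), vocab, policy, prov_ctx, pub_meta)


class TestAssemble:
    def test_four_named_graphs(self, one_np):
        graphs = one_np.bundle().graph_iris()
        assert len(graphs) == 4

    def test_head_has_exactly_four_statements(self, one_np):
        assert len(one_np.head) == 4

    def test_assembling_same_inputs_twice_is_identical(self, vocab, policy, prov_ctx, pub_meta):
        rec = OverlapRecord(25, "pr1", "poised_promoter")
        a = build_nanopub(rec, vocab, policy, prov_ctx, pub_meta)
        b = build_nanopub(rec, vocab, policy, prov_ctx, pub_meta)
        assert a.bundle() == b.bundle()

    def test_assemble_rehomes_independent_graphs(self, vocab, policy, prov_ctx, pub_meta):
        """Graphs built with their own IRIs are renamed under the nanopub IRI
        and cross-references follow the renaming."""
        rec = DEGeneRecord(2280)
        assertion = build_de_assertion(rec, vocab, policy)
        old_assertion_iri = next(iter(assertion.graph_iris()))
        provenance = build_provenance_graph(old_assertion_iri, prov_ctx, policy)
        pubinfo = build_pubinfo_graph(
            Iri("https://example.org/placeholder"), pub_meta, policy=policy
        )
        np = assemble(assertion, provenance, pubinfo, policy, "degene-2280")
        assert validate(np).ok
        assert np.nanopub_iri == mint_iri(policy, "nanopub", "degene-2280")

    def test_empty_assertion_is_an_assembly_error(self, vocab, policy, prov_ctx, pub_meta):
        provenance = build_provenance_graph(
            Iri("https://example.org/a#assertion"), prov_ctx, policy
        )
        pubinfo = build_pubinfo_graph(Iri("https://example.org/a"), pub_meta, policy=policy)
        with pytest.raises(AssemblyError):
            assemble(GraphBundle(), provenance, pubinfo, policy, "k")


class TestValidate:
    def test_well_formed_nanopub_has_empty_report(self, one_np):
        report = validate(one_np)
        assert report.ok and report.violations == ()

    def test_provenance_without_assertion_link_is_flagged(self, one_np):
        broken = Nanopublication(
            nanopub_iri=one_np.nanopub_iri,
            head=one_np.head,
            assertion=one_np.assertion,
            provenance=GraphBundle(
                q for q in one_np.provenance.quads
                if one_np.graph_iris["assertion"] not in (q.subject, q.object)
            ),
            pubinfo=one_np.pubinfo,
        )
        codes = {c for c, _, _ in validate(broken).violations}
        assert "PROV_NO_ASSERTION_LINK" in codes

    def test_single_quad_deletions_flagged_iff_quad_required(self, one_np):
        """Deletion fuzz: removing one quad must trip validation exactly when
        the quad is structurally required (any head statement, the last
        assertion quad, or the last provenance mention of the assertion
        graph / pubinfo mention of the nanopub)."""
        assertion_iri = one_np.graph_iris["assertion"]
        np_iri = one_np.nanopub_iri

        def mentions(bundle, target):
            return [
                q for q in bundle.quads if target in (q.subject, q.object)
            ]

        rng = random.Random(0)
        all_quads = sorted(
            one_np.bundle().quads,
            key=lambda q: (q.graph.value, q.subject.value, q.predicate.value),
        )
        for q in rng.sample(all_quads, k=len(all_quads)):
            part = next(
                name
                for name, b in (
                    ("head", one_np.head),
                    ("assertion", one_np.assertion),
                    ("provenance", one_np.provenance),
                    ("pubinfo", one_np.pubinfo),
                )
                if q in b.quads
            )
            required = (
                part == "head"
                or (part == "assertion" and len(one_np.assertion) == 1)
                or (
                    part == "provenance"
                    and len(mentions(one_np.provenance, assertion_iri)) == 1
                    and q in mentions(one_np.provenance, assertion_iri)
                )
                or (
                    part == "pubinfo"
                    and len(mentions(one_np.pubinfo, np_iri)) == 1
                    and q in mentions(one_np.pubinfo, np_iri)
                )
            )
            mutated = Nanopublication(
                nanopub_iri=one_np.nanopub_iri,
                head=GraphBundle(one_np.head.quads - {q}),
                assertion=GraphBundle(one_np.assertion.quads - {q}),
                provenance=GraphBundle(one_np.provenance.quads - {q}),
                pubinfo=GraphBundle(one_np.pubinfo.quads - {q}),
            )
            assert (not validate(mutated).ok) == required, (part, q)


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["trig", "nquads"])
    def test_single_nanopub_round_trip(self, one_np, tmp_path, dialect):
        path = tmp_path / f"np.{dialect}"
        write_nanopub(one_np, path, dialect)
        again = read_nanopub(path, dialect)
        assert again.bundle() == one_np.bundle()
        assert again.nanopub_iri == one_np.nanopub_iri

    def test_three_graph_document_is_a_structure_error(self, one_np, tmp_path):
        partial = one_np.head.union(one_np.assertion, one_np.provenance)
        path = tmp_path / "broken.trig"
        path.write_text(write_quads(partial, "trig"), encoding="utf-8")
        with pytest.raises(StructureError):
            read_nanopub(path)

    def test_hundred_nanopub_corpus_recovered(self, vocab, policy, prov_ctx, pub_meta, tmp_path):
        records = [DEGeneRecord(1000 + i) for i in range(100)]
        corpus = build_corpus(records, [], vocab, policy, prov_ctx, pub_meta)
        path = tmp_path / "corpus.trig"
        write_corpus(corpus, path)
        again = read_corpus(path)
        assert len(again) == 100
        assert {np.nanopub_iri for np in again} == {np.nanopub_iri for np in corpus}
        for np in again:
            assert validate(np).ok

    def test_corpus_graphs_are_disjoint_by_graph_iri(self, table2_corpus):
        seen: dict[str, str] = {}
        for np in table2_corpus:
            for part, iri in np.graph_iris.items():
                assert iri.value not in seen
                seen[iri.value] = np.nanopub_iri.value

    def test_corpus_size_is_row_counts_sum(self, table2_bundle, table2_corpus):
        expected = len(table2_bundle.de_table) + len(table2_bundle.overlap_table)
        assert len(table2_corpus) == expected
        assert all(validate(np).ok for np in table2_corpus)

    def test_head_links_resolve_to_the_member_graphs(self, one_np, tmp_path):
        path = tmp_path / "np.trig"
        write_nanopub(one_np, path)
        again = read_nanopub(path)
        linked = {
            q.object.value
            for q in again.head.quads
            if q.predicate == NP_HAS_ASSERTION
        }
        assert linked == {again.graph_iris["assertion"].value}
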