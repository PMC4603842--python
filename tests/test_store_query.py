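"""Store loading, canned queries, closure materialization, integration."""

import random

import pytest

from nanopubkit.assembler import build_corpus
from nanopubkit.config import RDFS_SUBCLASSOF
from nanopubkit.errors import (
    CycleError,
    IntegrationError,
    MappingError,
    ValidationError,
)
from nanopubkit.rdf_core import GraphBundle, Iri, Quad
from nanopubkit.store_query import (
    DrugTargetRow,
    FixtureGraphs,
    GoSeedConfig,
    QuadStore,
    filter_psa,
    integrate_drug_targets,
    map_go_uri,
    materialize_go_closure,
    query_de_genes,
    query_genes_by_region,
)
from nanopubkit.synthetic_data import build_store
from nanopubkit.templates import DEGeneRecord, OverlapRecord

OBO_GO = "http://purl.obolibrary.org/obo/GO_{accession}"
B2R_GO = "http://bio2rdf.org/go:{accession}"


def _go_bundle(edges, graph=FixtureGraphs().go_ontology):
    def iri(acc):
        return Iri(OBO_GO.format(accession=acc))

    return GraphBundle(Quad(iri(c), RDFS_SUBCLASSOF, iri(p), graph) for c, p in edges)


class TestLoad:
    def test_empty_load_leaves_store_unchanged(self):
        store = QuadStore()
        store.load(GraphBundle(), source_id="empty")
        assert len(store) == 0

    def test_loading_twice_is_idempotent(self, table2_corpus):
        store = QuadStore()
        store.load(table2_corpus, source_id="corpus")
        n = len(store)
        store.load(table2_corpus, source_id="corpus-again")
        assert len(store) == n

    def test_n_nanopubs_give_4n_named_graphs(self, table2_corpus):
        store = QuadStore()
        store.load(table2_corpus, source_id="corpus")
        assert len(store.graph_iris()) == 4 * len(table2_corpus)


class TestCannedQueries:
    def test_de_genes_match_the_input_table(self, vocab, policy, prov_ctx, pub_meta):
        ids = [1001, 1002, 1003, 1004, 1005, 1006, 1007, 1008, 1009, 1010]
        corpus = build_corpus(
            [DEGeneRecord(i) for i in ids], [], vocab, policy, prov_ctx, pub_meta
        )
        store = QuadStore().load(corpus)
        assert query_de_genes(store, vocab) == {vocab.gene_iri(i) for i in ids}

    def test_empty_store_returns_empty_set(self, vocab):
        assert query_de_genes(QuadStore(), vocab) == set()

    def test_duplicate_rows_collapse_to_set_semantics(self, vocab, policy, prov_ctx, pub_meta):
        corpus = build_corpus(
            [DEGeneRecord(1001), DEGeneRecord(1001)], [], vocab, policy, prov_ctx, pub_meta
        )
        store = QuadStore().load(corpus)
        assert query_de_genes(store, vocab) == {vocab.gene_iri(1001)}

    def test_all_mode_region_filter_matches_brute_force(self, vocab, policy, prov_ctx, pub_meta):
        """Genes A,B carry cpg+poised; C carries cpg only."""
        rows = [
            OverlapRecord(1, "pr1", "cpg_island"),
            OverlapRecord(1, "pr1", "poised_promoter"),
            OverlapRecord(2, "pr2", "cpg_island"),
            OverlapRecord(2, "pr2", "poised_promoter"),
            OverlapRecord(3, "pr3", "cpg_island"),
        ]
        corpus = build_corpus([], rows, vocab, policy, prov_ctx, pub_meta)
        store = QuadStore().load(corpus)
        both = query_genes_by_region(store, ["cpg_island", "poised_promoter"], "all", vocab)
        assert both == {vocab.gene_iri(1), vocab.gene_iri(2)}
        any_ = query_genes_by_region(
            store,
            ["cpg_island", "poised_promoter", "active_promoter", "weak_promoter", "heterochromatic"],
            "any",
            vocab,
        )
        assert any_ == {vocab.gene_iri(1), vocab.gene_iri(2), vocab.gene_iri(3)}

    def test_empty_kind_set_is_rejected(self, table2_store):
        with pytest.raises(ValidationError):
            query_genes_by_region(table2_store, [], "all")

    def test_unknown_kind_is_rejected(self, table2_store):
        with pytest.raises(ValidationError):
            query_genes_by_region(table2_store, ["enhancer"], "any")


class TestGoUriMapping:
    def test_obo_to_bio2rdf_preserves_accession(self):
        mapped = map_go_uri(Iri("http://purl.obolibrary.org/obo/GO_0006914"), OBO_GO, B2R_GO)
        assert mapped == Iri("http://bio2rdf.org/go:0006914")

    def test_map_then_reverse_map_is_identity(self):
        term = Iri("http://purl.obolibrary.org/obo/GO_0010498")
        assert map_go_uri(map_go_uri(term, OBO_GO, B2R_GO), B2R_GO, OBO_GO) == term

    def test_non_matching_iri_is_a_mapping_error(self):
        with pytest.raises(MappingError):
            map_go_uri(Iri("http://bio2rdf.org/geneid:25"), OBO_GO, B2R_GO)


class TestClosure:
    def test_toy_tree_materializes_all_descendants(self):
        # autophagy with 2 children, 1 grandchild -> 4 terms for that seed
        edges = [
            ("9000001", "0006914"),
            ("9000002", "0006914"),
            ("9000003", "9000001"),
        ]
        store = QuadStore().load(_go_bundle(edges), source_id="go")
        seeds = GoSeedConfig(seeds=("GO:0006914",))
        closure = materialize_go_closure(store, seeds=seeds)
        pairs = [q for q in closure.quads if q.predicate == seeds.closure_predicate]
        assert len(pairs) == 4
        assert all(q.object == Iri("http://bio2rdf.org/go:0006914") for q in pairs)
        assert {q.subject.value for q in pairs} == {
            "http://bio2rdf.org/go:0006914",
            "http://bio2rdf.org/go:9000001",
            "http://bio2rdf.org/go:9000002",
            "http://bio2rdf.org/go:9000003",
        }

    def test_leaf_seed_maps_only_itself(self):
        store = QuadStore().load(_go_bundle([("9000001", "0006914")]), source_id="go")
        seeds = GoSeedConfig(seeds=("GO:0006457",))
        with pytest.warns(UserWarning):
            closure = materialize_go_closure(store, seeds=seeds)
        pairs = [q for q in closure.quads if q.predicate == seeds.closure_predicate]
        assert {(q.subject.value, q.object.value) for q in pairs} == {
            ("http://bio2rdf.org/go:0006457", "http://bio2rdf.org/go:0006457")
        }

    def test_diamond_term_appears_once_per_seed_ancestor(self):
        # one term beneath both seeds
        edges = [("9000009", "0006914"), ("9000009", "0006457")]
        store = QuadStore().load(_go_bundle(edges), source_id="go")
        seeds = GoSeedConfig(seeds=("GO:0006914", "GO:0006457"))
        closure = materialize_go_closure(store, seeds=seeds)
        shared = [
            q for q in closure.quads
            if q.subject == Iri("http://bio2rdf.org/go:9000009")
            and q.predicate == seeds.closure_predicate
        ]
        assert {q.object.value for q in shared} == {
            "http://bio2rdf.org/go:0006914",
            "http://bio2rdf.org/go:0006457",
        }

    def test_matches_traversal_oracle_on_random_dags(self):
        rng = random.Random(11)
        for trial in range(10):
            n = rng.randint(10, 120)
            accs = [f"9{trial:02d}{i:04d}" for i in range(n)]
            edges = []
            for i in range(1, n):
                for p in rng.sample(range(i), k=min(i, rng.randint(1, 2))):
                    edges.append((accs[i], accs[p]))
            store = QuadStore().load(_go_bundle(edges), source_id="go")
            seed_acc = accs[rng.randint(0, 3)]
            seeds = GoSeedConfig(seeds=(f"GO:{seed_acc}",))
            closure = materialize_go_closure(store, seeds=seeds)
            got = {
                q.subject.value.rsplit(":", 1)[1]
                for q in closure.quads
                if q.predicate == seeds.closure_predicate
            }
            # independent oracle: brute-force reachability on reversed edges
            down = {}
            for c, p in edges:
                down.setdefault(p, set()).add(c)
            expected, stack = {seed_acc}, [seed_acc]
            while stack:
                for c in down.get(stack.pop(), ()):
                    if c not in expected:
                        expected.add(c)
                        stack.append(c)
            assert got == expected

    def test_cyclic_ontology_fails_loudly(self):
        edges = [("9000001", "9000002"), ("9000002", "9000001")]
        store = QuadStore().load(_go_bundle(edges), source_id="go")
        with pytest.raises(CycleError):
            materialize_go_closure(store, seeds=GoSeedConfig(seeds=("GO:9000001",)))


class TestIntegration:
    def test_worked_example_contains_published_rows(self, table2_store):
        rows = integrate_drug_targets(table2_store)
        pairs = {(r.gene_symbol, r.drug_name) for r in rows if r.drug is not None}
        assert ("ABL1", "Imatinib") in pairs
        assert ("PSMD1", "Bortezomib") in pairs
        abl1 = [r for r in rows if r.gene_symbol == "ABL1"]
        assert all(r.target == Iri("http://bio2rdf.org/drugbank_target:17") for r in abl1)
        assert all(r.go_label == "autophagy" for r in abl1)

    def test_gene_absent_from_annotations_yields_no_rows(self, table2_bundle):
        fixtures = FixtureGraphs()
        stripped = GraphBundle(
            q for q in table2_bundle.annotation_graph.quads
            if q.subject != Iri("http://bio2rdf.org/geneid:25")
        )
        import dataclasses

        bundle = dataclasses.replace(table2_bundle, annotation_graph=stripped)
        store, _ = build_store(bundle)
        rows = integrate_drug_targets(store)
        assert not any(r.gene_symbol == "ABL1" for r in rows)

    def test_missing_fixture_graph_names_the_stage(self, table2_corpus):
        store = QuadStore().load(table2_corpus)
        with pytest.raises(IntegrationError) as exc:
            integrate_drug_targets(store)
        assert exc.value.stage == "go-closure"

    def test_staged_equals_composed(self, table2_store):
        staged = integrate_drug_targets(table2_store, method="staged")
        composed = integrate_drug_targets(table2_store, method="composed")
        assert staged == composed

    def test_adding_drug_triples_never_removes_rows(self, table2_bundle):
        import dataclasses

        from nanopubkit.config import RDFS_LABEL
        from nanopubkit.rdf_core import LiteralValue

        fixtures = FixtureGraphs()
        store, _ = build_store(table2_bundle)
        before = set(integrate_drug_targets(store))
        extra = GraphBundle(
            [
                Quad(
                    Iri("http://bio2rdf.org/drugbank:DB99999"),
                    fixtures.drug_target_pred,
                    Iri("http://bio2rdf.org/drugbank_target:1524"),
                    fixtures.drug_targets,
                ),
                Quad(
                    Iri("http://bio2rdf.org/drugbank:DB99999"),
                    RDFS_LABEL,
                    LiteralValue("NewDrug"),
                    fixtures.drug_targets,
                ),
            ]
        )
        store.load(extra, source_id="more-drugs")
        after = set(integrate_drug_targets(store))
        # no gene/target association is ever lost, and no drug-level row is
        # lost (a bare-target row may be superseded by its new drug rows)
        key = lambda rows: {(r.gene, r.target) for r in rows}
        assert key(before) <= key(after)
        drug_level = lambda rows: {r for r in rows if r.drug is not None}
        assert drug_level(before) <= drug_level(after)
        assert any(r.drug_name == "NewDrug" for r in after)


class TestPsaFilter:
    def _row(self, psa):
        return DrugTargetRow(
            gene=Iri("http://bio2rdf.org/geneid:25"),
            gene_symbol="ABL1",
            go_label="autophagy",
            target=Iri("http://bio2rdf.org/drugbank_target:17"),
            drug=Iri("http://bio2rdf.org/drugbank:DB00619"),
            drug_name="Imatinib",
            psa=psa,
        )

    def test_threshold_is_strict(self):
        kept = filter_psa([self._row(59.9), self._row(60.0), self._row(60.1)])
        assert [r.psa for r in kept] == [59.9]

    def test_empty_input_gives_empty_output(self):
        assert filter_psa([]) == []

    def test_missing_psa_keep_policy_warns_per_row(self):
        rows = [self._row(None), self._row(None), self._row(None)]
        with pytest.warns(UserWarning) as record:
            kept = filter_psa(rows, missing="keep")
        assert kept == rows
        assert len(record) == 3

    def test_missing_psa_drop_policy_removes_rows(self):
        with pytest.warns(UserWarning):
            assert filter_psa([self._row(None)], missing="drop") == []
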