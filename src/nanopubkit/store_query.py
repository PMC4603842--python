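"""Local quad store, canned queries, GO-closure materialization and the
drug-target integration pipeline.

The integration mirrors a five-source linked-data join: differentially
expressed genes are read from the nanopublication assertions, filtered by
their promoter/region overlap nanopublications, joined to a GO-annotation
source through a *materialized* subclass closure of four seed biological
processes (proteasomal protein catabolic process GO:0010498, autophagy
GO:0006914, protein folding GO:0006457, protein unfolding GO:0043335),
restricted to human-taxon genes, and finally joined to DrugBank-style
targets and drugs.  Resulting targets can be prioritized for blood–brain-
barrier permeability by their polar surface area (PSA, Å²; strictly below
60 by default).

Because the GO ontology and the annotation source use different IRI schemes
for the same accession, closure terms are rewritten into the annotation
namespace before they are stored — the closure lives in its own named graph
so the expensive traversal runs once and the main query stays a plain join.

Every stage is an individually invocable function backed by a canned SPARQL
query shipped as a text file; a single composed query covering all five
sources is also provided and must return the same rows as the staged path.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from string import Template
from typing import Iterable, Literal, Sequence

import networkx as nx
from rdflib import Dataset, URIRef

from .assembler import Nanopublication
from .config import BIO2RDF, RDFS_LABEL, RDFS_SUBCLASSOF
from .errors import CycleError, IntegrationError, MappingError, ValidationError
from .ontology_ext import subclass_descendants
from .rdf_core import GraphBundle, Iri, LiteralValue, Quad, from_dataset
from .templates import CPG_ISLAND, REGION_KINDS, VocabularyConfig

__all__ = [
    "QuadStore",
    "GoSeedConfig",
    "FixtureGraphs",
    "DrugTargetRow",
    "load_query",
    "query_de_genes",
    "query_genes_by_region",
    "materialize_go_closure",
    "map_go_uri",
    "integrate_drug_targets",
    "filter_psa",
    "rows_to_tsv",
    "rows_from_tsv",
]

DEFAULT_GO_SEEDS = ("GO:0010498", "GO:0006914", "GO:0006457", "GO:0043335")


@dataclass(frozen=True)
class GoSeedConfig:
    """Seed GO processes and the IRI schemes on either side of the mapping."""

    seeds: tuple[str, ...] = DEFAULT_GO_SEEDS
    go_namespace_ontology: str = "http://purl.obolibrary.org/obo/GO_{accession}"
    go_namespace_annotation: str = BIO2RDF + "go:{accession}"
    closure_graph: Iri = Iri("urn:x-nanopubkit:go-closure")
    closure_predicate: Iri = Iri("urn:x-nanopubkit:vocab:has-seed-ancestor")

    def seed_accession(self, seed: str) -> str:
        if not re.fullmatch(r"GO:\d{7}", seed):
            raise ValidationError(f"not a GO accession: {seed!r}")
        return seed.split(":", 1)[1]

    def seed_ontology_iri(self, seed: str) -> Iri:
        return Iri(self.go_namespace_ontology.format(accession=self.seed_accession(seed)))

    def seed_annotation_iri(self, seed: str) -> Iri:
        return Iri(self.go_namespace_annotation.format(accession=self.seed_accession(seed)))


@dataclass(frozen=True)
class FixtureGraphs:
    """Well-known named-graph IRIs of the multi-source fixture datasets, and
    the artifact-defined predicates used inside them."""

    go_ontology: Iri = Iri("urn:x-fixture:go-ontology")
    go_annotations: Iri = Iri("urn:x-fixture:go-annotations")
    gene_info: Iri = Iri("urn:x-fixture:gene-info")
    drug_targets: Iri = Iri("urn:x-fixture:drug-targets")
    go_term_pred: Iri = Iri(BIO2RDF + "goa_vocabulary:go-term")
    symbol_pred: Iri = Iri(BIO2RDF + "geneid_vocabulary:symbol")
    taxon_pred: Iri = Iri(BIO2RDF + "geneid_vocabulary:taxid")
    human_taxon: Iri = Iri(BIO2RDF + "taxonomy:9606")
    target_gene_pred: Iri = Iri(BIO2RDF + "drugbank_vocabulary:gene")
    drug_target_pred: Iri = Iri(BIO2RDF + "drugbank_vocabulary:target")
    psa_pred: Iri = Iri(BIO2RDF + "drugbank_vocabulary:psa")
    description_pred: Iri = Iri("http://purl.org/dc/terms/description")


def _row_sort_key(row: "DrugTargetRow") -> tuple:
    return (
        row.gene_symbol,
        row.gene.value,
        row.go_label or "",
        row.target.value,
        row.drug.value if row.drug else "",
    )


@dataclass(frozen=True)
class DrugTargetRow:
    """One row of the integration result (Table-layout: gene, symbol, GO
    process label, target, drug, drug name, optional PSA in Å²)."""

    gene: Iri
    gene_symbol: str
    go_label: str | None
    target: Iri
    drug: Iri | None = None
    drug_name: str | None = None
    psa: float | None = None


class QuadStore:
    """A local named-graph store over an rdflib dataset (union default graph).

    Loading is idempotent at quad level (RDF set semantics) and tracked per
    source id for error reporting.
    """

    def __init__(self) -> None:
        self._ds = Dataset(default_union=True)
        self.sources: set[str] = set()

    def __len__(self) -> int:
        return sum(1 for _ in self._ds.quads((None, None, None, None)))

    def graph_iris(self) -> set[Iri]:
        return {
            Iri(str(g.identifier))
            for g in self._ds.graphs()
            if str(g.identifier) != "urn:x-rdflib:default" and len(g)
        }

    def load(
        self,
        source: GraphBundle | Nanopublication | Iterable[Nanopublication],
        source_id: str = "anonymous",
    ) -> "QuadStore":
        if isinstance(source, GraphBundle):
            bundle = source
        elif isinstance(source, Nanopublication):
            bundle = source.bundle()
        else:
            nps = list(source)
            bundle = GraphBundle()
            if nps:
                bundle = bundle.union(*(np.bundle() for np in nps))
        for q in bundle.quads:
            self._ds.graph(URIRef(q.graph.value)).add(
                (
                    URIRef(q.subject.value),
                    URIRef(q.predicate.value),
                    _to_rdflib(q.object),
                )
            )
        self.sources.add(source_id)
        return self

    def bundle(self, graph_iri: Iri | None = None) -> GraphBundle:
        if graph_iri is None:
            return from_dataset(self._ds)
        sub = Dataset(default_union=True)
        g = sub.graph(URIRef(graph_iri.value))
        for t in self._ds.graph(URIRef(graph_iri.value)):
            g.add(t)
        return from_dataset(sub)

    def query(self, sparql: str):
        return self._ds.query(sparql)

    def has_graph(self, graph_iri: Iri) -> bool:
        return len(self._ds.graph(URIRef(graph_iri.value))) > 0


def _to_rdflib(node):
    from .rdf_core import _to_rdflib_node

    return _to_rdflib_node(node)


def load_query(name: str, **bindings: str) -> str:
    """Load a canned SPARQL query text file and fill in its parameters."""
    text = resources.files("nanopubkit.queries").joinpath(f"{name}.rq").read_text("utf-8")
    return Template(text).substitute(**bindings)


# ---------------------------------------------------------------------------
# canned queries


def query_de_genes(store: QuadStore, vocab: VocabularyConfig | None = None) -> set[Iri]:
    """Exactly the genes appearing in differential-expression assertions."""
    vocab = vocab or VocabularyConfig()
    q = load_query(
        "de_genes",
        assoc_class=vocab.de_association_class.value,
        refers_to=vocab.refers_to.value,
        disease=vocab.hd_disease.value,
    )
    return {Iri(str(row.gene)) for row in store.query(q)}


def _genes_with_kind(store: QuadStore, vocab: VocabularyConfig, kind: str) -> set[Iri]:
    if kind == CPG_ISLAND:
        q = load_query(
            "region_cpg",
            associated_with=vocab.associated_with.value,
            overlaps_with=vocab.overlaps_with.value,
            cpg_class=vocab.cpg_island_class.value,
        )
    else:
        q = load_query(
            "region_state",
            associated_with=vocab.associated_with.value,
            overlaps_with=vocab.overlaps_with.value,
            has_state=vocab.has_state.value,
            state=vocab.state_iri(kind).value,
        )
    return {Iri(str(row.gene)) for row in store.query(q)}


def query_genes_by_region(
    store: QuadStore,
    region_kinds: Iterable[str],
    mode: Literal["any", "all"] = "any",
    vocab: VocabularyConfig | None = None,
) -> set[Iri]:
    """Genes whose overlap assertions cover any/all of the requested kinds.

    The intersection over an empty kind set would be vacuously everything,
    so an empty request is rejected instead.
    """
    vocab = vocab or VocabularyConfig()
    kinds = list(region_kinds)
    if not kinds:
        raise ValidationError("region_kinds must be non-empty")
    unknown = set(kinds) - REGION_KINDS
    if unknown:
        raise ValidationError(f"unknown region kind(s): {sorted(unknown)}")
    if mode not in ("any", "all"):
        raise ValidationError(f"mode must be 'any' or 'all', got {mode!r}")
    sets = [_genes_with_kind(store, vocab, k) for k in kinds]
    result = set(sets[0])
    for s in sets[1:]:
        result = result | s if mode == "any" else result & s
    return result


def _genes_with_any_overlap(store: QuadStore, vocab: VocabularyConfig) -> set[Iri]:
    q = load_query(
        "region_any",
        associated_with=vocab.associated_with.value,
        overlaps_with=vocab.overlaps_with.value,
    )
    return {Iri(str(row.gene)) for row in store.query(q)}


# ---------------------------------------------------------------------------
# GO closure materialization and URI mapping


def map_go_uri(term: Iri, from_ns: str, to_ns: str) -> Iri:
    """Accession-preserving rewrite between GO IRI schemes.

    The namespace patterns carry one ``{accession}`` slot, e.g. mapping
    ``.../obo/GO_0006914`` to ``http://bio2rdf.org/go:0006914``.
    """
    for pattern in (from_ns, to_ns):
        if "{accession}" not in pattern:
            raise MappingError(f"namespace pattern lacks an {{accession}} slot: {pattern!r}")
    pre, _, post = from_ns.partition("{accession}")
    v = term.value
    if not (v.startswith(pre) and v.endswith(post) and len(v) > len(pre) + len(post)):
        raise MappingError(f"IRI {v!r} does not match namespace pattern {from_ns!r}")
    accession = v[len(pre) : len(v) - len(post)] if post else v[len(pre) :]
    return Iri(to_ns.format(accession=accession))


def _check_acyclic(bundle: GraphBundle) -> None:
    g = nx.DiGraph()
    for q in bundle.quads:
        if q.predicate == RDFS_SUBCLASSOF and isinstance(q.object, Iri):
            g.add_edge(q.subject.value, q.object.value)
    if g.number_of_edges() and not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CycleError(f"subClassOf cycle in ontology fixture: {cycle[0][0]} ...")


def materialize_go_closure(
    store: QuadStore,
    go_ontology_graph: Iri | None = None,
    seeds: GoSeedConfig | None = None,
    fixtures: FixtureGraphs | None = None,
) -> GraphBundle:
    """Materialize (term, seed-ancestor) pairs into a dedicated named graph.

    For each seed, every subclass descendant in the GO ontology graph
    (including the seed itself) is rewritten into the annotation namespace
    and linked to the (also rewritten) seed; seed labels are copied so the
    integration result can report the process name.  A seed missing from
    the ontology stays in the closure with no descendants, with a warning.
    """
    seeds = seeds or GoSeedConfig()
    fixtures = fixtures or FixtureGraphs()
    graph_iri = go_ontology_graph or fixtures.go_ontology
    onto = store.bundle(graph_iri)
    _check_acyclic(onto)
    cg = seeds.closure_graph
    quads: list[Quad] = []
    labels = {
        q.subject: q.object
        for q in onto.quads
        if q.predicate == RDFS_LABEL and isinstance(q.object, LiteralValue)
    }
    for seed in seeds.seeds:
        seed_iri = seeds.seed_ontology_iri(seed)
        seed_ann = seeds.seed_annotation_iri(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # absence is re-reported per seed below
            descendants = subclass_descendants(onto, seed_iri)
        if not descendants:
            warnings.warn(f"seed {seed} absent from ontology graph; kept with no descendants")
            descendants = {seed_iri}
        for term in descendants:
            mapped = map_go_uri(
                term, seeds.go_namespace_ontology, seeds.go_namespace_annotation
            )
            quads.append(Quad(mapped, seeds.closure_predicate, seed_ann, cg))
        if seed_iri in labels:
            quads.append(Quad(seed_ann, RDFS_LABEL, labels[seed_iri], cg))
    bundle = GraphBundle(quads)
    store.load(bundle, source_id="go-closure")
    return bundle


# ---------------------------------------------------------------------------
# integration


def _require_graph(store: QuadStore, graph: Iri, stage: str) -> None:
    if not store.has_graph(graph):
        raise IntegrationError(
            f"stage {stage!r} needs fixture graph {graph.value}, which is empty or missing",
            stage=stage,
        )


def integrate_drug_targets(
    store: QuadStore,
    seeds: GoSeedConfig | None = None,
    vocab: VocabularyConfig | None = None,
    fixtures: FixtureGraphs | None = None,
    region_kinds: Iterable[str] | None = None,
    region_mode: Literal["any", "all"] = "any",
    method: Literal["staged", "composed"] = "staged",
) -> list[DrugTargetRow]:
    """The drug-target integration over nanopubs + fixture sources.

    Stages run in order: DE genes → region filter → GO-annotation join via
    the materialized closure → human-taxon symbol lookup → target and drug
    join.  ``method='composed'`` runs the single composed SPARQL query
    instead (only for the default any-region filter) and is the
    cross-check for the staged path.
    """
    seeds = seeds or GoSeedConfig()
    vocab = vocab or VocabularyConfig()
    fixtures = fixtures or FixtureGraphs()

    if not store.has_graph(seeds.closure_graph):
        _require_graph(store, fixtures.go_ontology, "go-closure")
        materialize_go_closure(store, fixtures.go_ontology, seeds, fixtures)
    _require_graph(store, fixtures.go_annotations, "go-annotation")
    _require_graph(store, fixtures.gene_info, "gene-info")
    _require_graph(store, fixtures.drug_targets, "drugbank")

    if method == "composed":
        if region_kinds is not None:
            raise ValidationError("the composed query only supports the any-region filter")
        return _integrate_composed(store, seeds, vocab, fixtures)

    # stage 1: differentially expressed genes
    genes = query_de_genes(store, vocab)
    # stage 2: promoter/region overlap filter
    if region_kinds is None:
        genes &= _genes_with_any_overlap(store, vocab)
    else:
        genes &= query_genes_by_region(store, region_kinds, region_mode, vocab)
    # stage 3: GO annotation through the closure
    q = load_query(
        "annotated_genes",
        annotation_graph=fixtures.go_annotations.value,
        go_term_pred=fixtures.go_term_pred.value,
        closure_graph=seeds.closure_graph.value,
        closure_pred=seeds.closure_predicate.value,
    )
    gene_seeds: set[tuple[Iri, Iri]] = {
        (Iri(str(row.gene)), Iri(str(row.seed)))
        for row in store.query(q)
        if Iri(str(row.gene)) in genes
    }
    # stage 4: human-taxon gene symbols
    q = load_query(
        "human_symbols",
        geneinfo_graph=fixtures.gene_info.value,
        symbol_pred=fixtures.symbol_pred.value,
        taxon_pred=fixtures.taxon_pred.value,
        human_taxon=fixtures.human_taxon.value,
    )
    symbols: dict[Iri, str] = {Iri(str(row.gene)): str(row.symbol) for row in store.query(q)}
    # stage 5: drug targets and drugs
    q = load_query(
        "drug_targets",
        drugtarget_graph=fixtures.drug_targets.value,
        target_gene_pred=fixtures.target_gene_pred.value,
        drug_target_pred=fixtures.drug_target_pred.value,
        psa_pred=fixtures.psa_pred.value,
    )
    target_rows: dict[Iri, list] = {}
    for row in store.query(q):
        target_rows.setdefault(Iri(str(row.gene)), []).append(row)

    seed_labels = _seed_labels(store, seeds)
    out: list[DrugTargetRow] = []
    for gene, seed in sorted(gene_seeds, key=lambda t: (t[0].value, t[1].value)):
        if gene not in symbols:
            continue
        for row in target_rows.get(gene, ()):
            out.append(
                DrugTargetRow(
                    gene=gene,
                    gene_symbol=symbols[gene],
                    go_label=seed_labels.get(seed),
                    target=Iri(str(row.target)),
                    drug=Iri(str(row.drug)) if row.drug is not None else None,
                    drug_name=str(row.drugname) if row.drugname is not None else None,
                    psa=float(row.psa) if row.psa is not None else None,
                )
            )
    return sorted(set(out), key=_row_sort_key)


def _seed_labels(store: QuadStore, seeds: GoSeedConfig) -> dict[Iri, str]:
    closure = store.bundle(seeds.closure_graph)
    return {
        q.subject: q.object.lexical
        for q in closure.quads
        if q.predicate == RDFS_LABEL and isinstance(q.object, LiteralValue)
    }


def _integrate_composed(
    store: QuadStore, seeds: GoSeedConfig, vocab: VocabularyConfig, fixtures: FixtureGraphs
) -> list[DrugTargetRow]:
    q = load_query(
        "integrate_composed",
        assoc_class=vocab.de_association_class.value,
        refers_to=vocab.refers_to.value,
        disease=vocab.hd_disease.value,
        associated_with=vocab.associated_with.value,
        overlaps_with=vocab.overlaps_with.value,
        annotation_graph=fixtures.go_annotations.value,
        go_term_pred=fixtures.go_term_pred.value,
        closure_graph=seeds.closure_graph.value,
        closure_pred=seeds.closure_predicate.value,
        geneinfo_graph=fixtures.gene_info.value,
        symbol_pred=fixtures.symbol_pred.value,
        taxon_pred=fixtures.taxon_pred.value,
        human_taxon=fixtures.human_taxon.value,
        drugtarget_graph=fixtures.drug_targets.value,
        target_gene_pred=fixtures.target_gene_pred.value,
        drug_target_pred=fixtures.drug_target_pred.value,
        psa_pred=fixtures.psa_pred.value,
    )
    out = []
    for row in store.query(q):
        out.append(
            DrugTargetRow(
                gene=Iri(str(row.gene)),
                gene_symbol=str(row.symbol),
                go_label=str(row.golabel) if row.golabel is not None else None,
                target=Iri(str(row.target)),
                drug=Iri(str(row.drug)) if row.drug is not None else None,
                drug_name=str(row.drugname) if row.drugname is not None else None,
                psa=float(row.psa) if row.psa is not None else None,
            )
        )
    return sorted(set(out), key=_row_sort_key)


# ---------------------------------------------------------------------------
# PSA prioritization


def filter_psa(
    rows: Sequence[DrugTargetRow],
    threshold: float = 60.0,
    missing: Literal["keep", "drop"] = "keep",
) -> list[DrugTargetRow]:
    """Keep rows with PSA strictly below the threshold (Å²).

    Rows without a PSA value are kept or dropped per ``missing`` and warned
    about either way — a missing descriptor is not evidence of permeability.
    """
    out: list[DrugTargetRow] = []
    for row in rows:
        if row.psa is None:
            warnings.warn(
                f"row for {row.gene_symbol} / {row.drug_name or row.target.value} has no PSA"
            )
            if missing == "keep":
                out.append(row)
            continue
        if row.psa < threshold:
            out.append(row)
    return out


_TSV_HEADER = "Gene\tGeneSymbol\tGoTerm\tTarget\tDrug\tDrugDescription\tPSA"


def rows_to_tsv(rows: Iterable[DrugTargetRow]) -> str:
    """Result rows in the canonical column order (plus a trailing PSA column)."""
    lines = [_TSV_HEADER]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.gene.value,
                    r.gene_symbol,
                    r.go_label or "",
                    r.target.value,
                    r.drug.value if r.drug else "",
                    r.drug_name or "",
                    "" if r.psa is None else f"{r.psa:g}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def rows_from_tsv(text: str) -> list[DrugTargetRow]:
    """Parse rows written by :func:`rows_to_tsv`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != _TSV_HEADER:
        raise ValidationError("result TSV must start with the canonical header")
    out = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 7:
            raise ValidationError(f"result TSV row has {len(parts)} columns, expected 7")
        gene, symbol, golabel, target, drug, name, psa = parts
        out.append(
            DrugTargetRow(
                gene=Iri(gene),
                gene_symbol=symbol,
                go_label=golabel or None,
                target=Iri(target),
                drug=Iri(drug) if drug else None,
                drug_name=name or None,
                psa=float(psa) if psa else None,
            )
        )
    return out
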