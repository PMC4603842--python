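"""Seeded generators for every input the pipeline consumes.

Two generators are provided.  :func:`generate` emulates the *shape* of the
study's result tables and of the knowledge-graph sources they were joined
with: a differential-expression gene table, a gene→promoter→region overlap
table, a toy GO subclass DAG rooted at the four seed biological processes, a
GO-annotation graph, a gene-info graph with taxon assignments, a
DrugBank-like target/drug graph with synthetic polar-surface-area values, a
Research-Object manifest and author metadata.  Everything is deterministic
per seed, and the generator keeps *truth* bookkeeping — which genes satisfy
which downstream condition — computed during generation, so queries can be
checked against an answer that never ran through the query engine.

:func:`table2_fixture` encodes the published worked example: eight
Huntington's-disease-deregulated genes (ABL1, FKBP1A, PPIF, PPIA, PPIB,
PPIC, TUBA4A, PSMD1), their GO processes, six DrugBank targets and the
twelve listed drugs.  PSA values are synthetic (none are published) and the
PPIA/PPIB/PPIC rows carry targets but no drugs, so they appear in
target-level but not drug-level projections.

Synthetic gene ids are drawn from a reserved high range (≥ 1 000 000 000)
to avoid colliding with real NCBI ids.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .assembler import Nanopublication, build_corpus
from .config import RDFS_LABEL, RDFS_SUBCLASSOF, RunConfig
from .context_graphs import EntityLink, ProvenanceContext, PublicationMeta
from .errors import NanopubKitError, ValidationError
from .ontology_ext import ChromatinStateKind
from .rdf_core import GraphBundle, Iri, LiteralValue, Quad
from .store_query import DrugTargetRow, FixtureGraphs, GoSeedConfig, QuadStore, _row_sort_key
from .templates import (
    CPG_ISLAND,
    DEGeneRecord,
    OverlapRecord,
    VocabularyConfig,
    default_vocabulary,
    records_from_tsv,
    records_to_tsv,
)

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "Truth",
    "generate",
    "table2_fixture",
    "write_fixture",
    "read_fixture",
    "build_store",
]

_GENE_ID_BASE = 1_000_000_000  # reserved range, clear of real NCBI gene ids

_SEED_LABELS = {
    "GO:0010498": "proteasomal protein catabolic process",
    "GO:0006914": "autophagy",
    "GO:0006457": "protein folding",
    "GO:0043335": "protein unfolding",
}

_DEFAULT_WEIGHTS = {
    CPG_ISLAND: 0.2,
    ChromatinStateKind.ACTIVE_PROMOTER.value: 0.2,
    ChromatinStateKind.WEAK_PROMOTER.value: 0.2,
    ChromatinStateKind.POISED_PROMOTER.value: 0.2,
    ChromatinStateKind.HETEROCHROMATIC.value: 0.2,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic study; defaults are the standard conditions."""

    n_genes: int = 200
    de_fraction: float = 0.5
    region_kind_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    go_depth: int = 3
    go_branching: int = 2
    fraction_genes_annotated_to_seeds: float = 0.6
    human_fraction: float = 0.9
    target_fraction: float = 0.8
    drugs_per_target: tuple[int, int] = (0, 3)
    psa_range: tuple[float, float] = (20.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValidationError("n_genes must be non-negative")
        for name in ("de_fraction", "fraction_genes_annotated_to_seeds",
                     "human_fraction", "target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        total = sum(self.region_kind_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"region_kind_weights must sum to 1, got {total}")
        lo, hi = self.drugs_per_target
        if lo < 0 or hi < lo:
            raise ValidationError("drugs_per_target must be a (lo, hi) count range")
        if self.psa_range[0] > self.psa_range[1]:
            raise ValidationError("psa_range must be (lo, hi)")
        if self.go_depth < 1 or self.go_branching < 1:
            raise ValidationError("go_depth and go_branching must be >= 1")


@dataclass(frozen=True)
class Truth:
    """Generator bookkeeping: the expected answer of each downstream query."""

    de_genes: tuple[str, ...]
    genes_by_region: Mapping[str, tuple[str, ...]]
    expected_rows: tuple[DrugTargetRow, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "de_genes": list(self.de_genes),
                "genes_by_region": {k: list(v) for k, v in self.genes_by_region.items()},
                "expected_rows": [
                    {
                        "gene": r.gene.value,
                        "gene_symbol": r.gene_symbol,
                        "go_label": r.go_label,
                        "target": r.target.value,
                        "drug": r.drug.value if r.drug else None,
                        "drug_name": r.drug_name,
                        "psa": r.psa,
                    }
                    for r in self.expected_rows
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Truth":
        data = json.loads(text)
        rows = tuple(
            DrugTargetRow(
                gene=Iri(d["gene"]),
                gene_symbol=d["gene_symbol"],
                go_label=d["go_label"],
                target=Iri(d["target"]),
                drug=Iri(d["drug"]) if d["drug"] else None,
                drug_name=d["drug_name"],
                psa=d["psa"],
            )
            for d in data["expected_rows"]
        )
        return cls(
            de_genes=tuple(data["de_genes"]),
            genes_by_region={k: tuple(v) for k, v in data["genes_by_region"].items()},
            expected_rows=rows,
        )


@dataclass(frozen=True)
class FixtureBundle:
    de_table: tuple[DEGeneRecord, ...]
    overlap_table: tuple[OverlapRecord, ...]
    go_graph: GraphBundle
    annotation_graph: GraphBundle
    geneinfo_graph: GraphBundle
    drugtarget_graph: GraphBundle
    ro_manifest: ProvenanceContext
    meta: PublicationMeta
    truth: Truth


def default_provenance_context() -> ProvenanceContext:
    base = "https://example.org/workflow/"
    return ProvenanceContext(
        workflow_activity_iri=Iri(base + "run/1"),
        research_object_iri=Iri("https://example.org/ro/hd-epigenomics-pack"),
        inputs=(
            EntityLink(Iri(base + "data/expression-matrix"),
                       Iri("https://example.org/ro/hd-epigenomics-pack/expression-matrix")),
            EntityLink(Iri(base + "data/cpg-track"),
                       Iri("https://example.org/ro/hd-epigenomics-pack/cpg-track")),
            EntityLink(Iri(base + "data/chromatin-track"),
                       Iri("https://example.org/ro/hd-epigenomics-pack/chromatin-track")),
        ),
        outputs=(
            EntityLink(Iri(base + "data/result-tables"),
                       Iri("https://example.org/ro/hd-epigenomics-pack/result-tables")),
        ),
        agent_iri=Iri("https://orcid.org/0000-0002-0000-0001"),
        execution_time="2015-02-09T12:00:00+00:00",
    )


def default_publication_meta() -> PublicationMeta:
    return PublicationMeta(
        authors=(
            Iri("https://orcid.org/0000-0002-0000-0001"),
            Iri("https://orcid.org/0000-0002-0000-0002"),
        ),
        contributors=(Iri("https://orcid.org/0000-0002-0000-0003"),),
        created="2015-02-09T00:00:00+00:00",
        version="1.0",
        license_iri=Iri("https://creativecommons.org/licenses/by/4.0/"),
    )


def _weighted_distinct_kinds(rng: random.Random, weights: Mapping[str, float], k: int) -> list[str]:
    kinds = [kind for kind, w in weights.items() if w > 0]
    probs = [weights[kind] for kind in kinds]
    chosen: list[str] = []
    while len(chosen) < min(k, len(kinds)):
        pick = rng.choices(kinds, weights=probs, k=1)[0]
        if pick not in chosen:
            chosen.append(pick)
    return chosen


def generate(
    spec: FixtureSpec,
    fixtures: FixtureGraphs | None = None,
    seeds: GoSeedConfig | None = None,
    vocab: VocabularyConfig | None = None,
) -> FixtureBundle:
    """Generate a complete, internally consistent fixture bundle.

    The same spec (including its seed) always yields byte-identical output.
    """
    if not isinstance(spec, FixtureSpec):
        raise ValidationError("generate() needs a FixtureSpec")
    fixtures = fixtures or FixtureGraphs()
    seeds = seeds or GoSeedConfig()
    vocab = vocab or VocabularyConfig()
    rng = random.Random(spec.seed)

    gene_ids = [_GENE_ID_BASE + i for i in range(spec.n_genes)]
    symbols = {g: f"SYNG{g - _GENE_ID_BASE}" for g in gene_ids}

    n_de = round(spec.n_genes * spec.de_fraction)
    de_genes = sorted(rng.sample(gene_ids, k=n_de))
    de_table = tuple(DEGeneRecord(g, symbols[g]) for g in de_genes)

    # overlaps: every DE gene gets one promoter with 1-2 region kinds
    overlap_rows: list[OverlapRecord] = []
    gene_kinds: dict[int, list[str]] = {}
    for g in de_genes:
        k = 1 + (1 if rng.random() < 0.5 else 0)
        kinds = _weighted_distinct_kinds(rng, spec.region_kind_weights, k)
        gene_kinds[g] = kinds
        for kind in kinds:
            overlap_rows.append(OverlapRecord(g, f"pr{g}", kind))
    overlap_table = tuple(overlap_rows)

    # toy GO DAG: each seed roots a tree of the requested depth/branching,
    # with occasional extra within-subtree parents (diamonds); plus an
    # off-seed subtree whose annotations must never reach the results
    og = fixtures.go_ontology
    go_quads: list[Quad] = []
    acc_counter = iter(range(9_000_000, 9_999_999))

    def onto_iri(acc: str) -> Iri:
        return Iri(seeds.go_namespace_ontology.format(accession=acc.split(":")[1]))

    subtree_terms: dict[str, list[str]] = {}
    for seed_acc in seeds.seeds:
        seed_iri = onto_iri(seed_acc)
        label = _SEED_LABELS.get(seed_acc, seed_acc)
        go_quads.append(Quad(seed_iri, RDFS_LABEL, LiteralValue(label, language="en"), og))
        level = [seed_acc]
        terms = [seed_acc]
        for _depth in range(spec.go_depth - 1):
            nxt: list[str] = []
            for parent in level:
                for _b in range(spec.go_branching):
                    child = f"GO:{next(acc_counter):07d}"
                    go_quads.append(
                        Quad(onto_iri(child), RDFS_SUBCLASSOF, onto_iri(parent), og)
                    )
                    go_quads.append(
                        Quad(
                            onto_iri(child),
                            RDFS_LABEL,
                            LiteralValue(f"synthetic process {child}", language="en"),
                            og,
                        )
                    )
                    if terms and rng.random() < 0.1:  # diamond within the subtree
                        extra = rng.choice(terms)
                        if extra != child and extra != parent:
                            go_quads.append(
                                Quad(onto_iri(child), RDFS_SUBCLASSOF, onto_iri(extra), og)
                            )
                    nxt.append(child)
                    terms.append(child)
            level = nxt
        subtree_terms[seed_acc] = terms
    off_terms: list[str] = []
    off_root = f"GO:{next(acc_counter):07d}"
    go_quads.append(
        Quad(onto_iri(off_root), RDFS_LABEL,
             LiteralValue("unrelated process", language="en"), og)
    )
    for _ in range(4):
        child = f"GO:{next(acc_counter):07d}"
        go_quads.append(Quad(onto_iri(child), RDFS_SUBCLASSOF, onto_iri(off_root), og))
        off_terms.append(child)
    off_terms.append(off_root)

    def ann_iri(acc: str) -> Iri:
        return Iri(seeds.go_namespace_annotation.format(accession=acc.split(":")[1]))

    # annotations: one GO term per gene; a configurable fraction of genes
    # land inside a seed subtree, the rest in the off-seed subtree
    ag = fixtures.go_annotations
    ann_quads: list[Quad] = []
    gene_seed: dict[int, str] = {}
    for g in gene_ids:
        if rng.random() < spec.fraction_genes_annotated_to_seeds:
            seed_acc = rng.choice(list(seeds.seeds))
            term = rng.choice(subtree_terms[seed_acc])
            gene_seed[g] = seed_acc
        else:
            term = rng.choice(off_terms)
        ann_quads.append(Quad(vocab.gene_iri(g), fixtures.go_term_pred, ann_iri(term), ag))

    # gene info: symbol for everyone, human taxon for most
    gg = fixtures.gene_info
    info_quads: list[Quad] = []
    human: set[int] = set()
    mouse_taxon = Iri("http://bio2rdf.org/taxonomy:10090")
    for g in gene_ids:
        gene = vocab.gene_iri(g)
        info_quads.append(Quad(gene, fixtures.symbol_pred, LiteralValue(symbols[g]), gg))
        if rng.random() < spec.human_fraction:
            human.add(g)
            info_quads.append(Quad(gene, fixtures.taxon_pred, fixtures.human_taxon, gg))
        else:
            info_quads.append(Quad(gene, fixtures.taxon_pred, mouse_taxon, gg))

    # drug targets: at most one target per gene, 0..k drugs per target
    dg = fixtures.drug_targets
    drug_quads: list[Quad] = []
    gene_target: dict[int, Iri] = {}
    target_drugs: dict[int, list[tuple[Iri, str, float]]] = {}
    drug_counter = 0
    for g in gene_ids:
        if rng.random() >= spec.target_fraction:
            continue
        target = Iri(f"http://bio2rdf.org/drugbank_target:9{g - _GENE_ID_BASE:06d}")
        gene_target[g] = target
        drug_quads.append(Quad(target, fixtures.target_gene_pred, vocab.gene_iri(g), dg))
        n_drugs = rng.randint(*spec.drugs_per_target)
        drugs: list[tuple[Iri, str, float]] = []
        for _ in range(n_drugs):
            drug_counter += 1
            drug = Iri(f"http://bio2rdf.org/drugbank:SYND{drug_counter:05d}")
            name = f"SynthDrug{drug_counter:05d}"
            psa = round(rng.uniform(*spec.psa_range), 1)
            drug_quads.append(Quad(drug, fixtures.drug_target_pred, target, dg))
            drug_quads.append(Quad(drug, RDFS_LABEL, LiteralValue(name), dg))
            drug_quads.append(
                Quad(drug, fixtures.psa_pred,
                     LiteralValue(repr(psa), datatype=Iri("http://www.w3.org/2001/XMLSchema#double")),
                     dg)
            )
            drugs.append((drug, name, psa))
        target_drugs[g] = drugs

    # truth bookkeeping, derived from the construction above
    de_iris = tuple(vocab.gene_iri(g).value for g in de_genes)
    by_region: dict[str, list[str]] = {k: [] for k in _DEFAULT_WEIGHTS}
    for g, kinds in gene_kinds.items():
        for kind in kinds:
            by_region[kind].append(vocab.gene_iri(g).value)
    expected: list[DrugTargetRow] = []
    for g in de_genes:  # the DE ∩ overlap ∩ seed-annotated ∩ human ∩ targeted join
        if g not in gene_kinds or g not in gene_seed or g not in human:
            continue
        if g not in gene_target:
            continue
        seed_acc = gene_seed[g]
        label = _SEED_LABELS.get(seed_acc, seed_acc)
        drugs = target_drugs.get(g, [])
        if not drugs:
            expected.append(
                DrugTargetRow(vocab.gene_iri(g), symbols[g], label, gene_target[g])
            )
        for drug, name, psa in drugs:
            expected.append(
                DrugTargetRow(
                    vocab.gene_iri(g), symbols[g], label, gene_target[g], drug, name, psa
                )
            )
    truth = Truth(
        de_genes=de_iris,
        genes_by_region={k: tuple(sorted(v)) for k, v in by_region.items()},
        expected_rows=tuple(sorted(expected, key=_row_sort_key)),
    )
    return FixtureBundle(
        de_table=de_table,
        overlap_table=overlap_table,
        go_graph=GraphBundle(go_quads),
        annotation_graph=GraphBundle(ann_quads),
        geneinfo_graph=GraphBundle(info_quads),
        drugtarget_graph=GraphBundle(drug_quads),
        ro_manifest=default_provenance_context(),
        meta=default_publication_meta(),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# the published worked example

_TABLE2 = (
    # gene_id, symbol, seed GO accession, annotated term, target id, drugs
    (25, "ABL1", "GO:0006914", "GO:0016236",
     17, (("DB00171", "Adenosine triphosphate"), ("DB00619", "Imatinib"),
          ("DB01254", "Dasatinib"), ("DB04868", "Nilotinib"))),
    (2280, "FKBP1A", "GO:0006457", "GO:0006457",
     768, (("DB00337", "Pimecrolimus"), ("DB00864", "Tacrolimus"),
           ("DB00877", "Sirolimus"))),
    (10105, "PPIF", "GO:0006457", "GO:0006457",
     2554, (("DB00172", "L-Proline"),)),
    (5478, "PPIA", "GO:0006457", "GO:0006457", 1524, ()),
    (5479, "PPIB", "GO:0006457", "GO:0006457", 4084, ()),
    (5480, "PPIC", "GO:0006457", "GO:0006457", 4085, ()),
    (7277, "TUBA4A", "GO:0006457", "GO:0006457",
     2539, (("DB00541", "Vincristine"), ("DB06772", "cabazitaxel"),
            ("DB01179", "Podofilox"))),
    (5707, "PSMD1", "GO:0010498", "GO:0010498",
     515, (("DB00188", "Bortezomib"),)),
)

#: Genes whose promoters additionally carry a poised chromatin state in the
#: worked example (exercises the cpg+poised canned query).
_TABLE2_POISED = (25, 2280)


def table2_fixture(
    fixtures: FixtureGraphs | None = None,
    seeds: GoSeedConfig | None = None,
    vocab: VocabularyConfig | None = None,
) -> FixtureBundle:
    """The packaged worked example: the published drug-target result set.

    ABL1 is annotated to macroautophagy (GO:0016236), a child of the
    autophagy seed, so the example only resolves through the subclass
    closure; every other gene is annotated to its seed directly.  PSA
    values are synthetic (deterministic), since none are published.
    """
    fixtures = fixtures or FixtureGraphs()
    seeds = seeds or GoSeedConfig()
    vocab = vocab or VocabularyConfig()
    rng = random.Random(42)  # synthetic PSA values only

    de_table = tuple(DEGeneRecord(g, sym) for g, sym, *_ in _TABLE2)
    overlap_rows = [OverlapRecord(g, f"pr{g}", CPG_ISLAND) for g, *_ in _TABLE2]
    overlap_rows += [
        OverlapRecord(g, f"pr{g}", ChromatinStateKind.POISED_PROMOTER.value)
        for g in _TABLE2_POISED
    ]

    og = fixtures.go_ontology

    def onto_iri(acc: str) -> Iri:
        return Iri(seeds.go_namespace_ontology.format(accession=acc.split(":")[1]))

    def ann_iri(acc: str) -> Iri:
        return Iri(seeds.go_namespace_annotation.format(accession=acc.split(":")[1]))

    go_quads = [
        Quad(onto_iri(acc), RDFS_LABEL, LiteralValue(label, language="en"), og)
        for acc, label in _SEED_LABELS.items()
    ]
    go_quads.append(Quad(onto_iri("GO:0016236"), RDFS_SUBCLASSOF, onto_iri("GO:0006914"), og))
    go_quads.append(
        Quad(onto_iri("GO:0016236"), RDFS_LABEL, LiteralValue("macroautophagy", language="en"), og)
    )

    ann_quads = [
        Quad(vocab.gene_iri(g), fixtures.go_term_pred, ann_iri(term), fixtures.go_annotations)
        for g, _sym, _seed, term, *_ in _TABLE2
    ]
    info_quads = []
    for g, sym, *_ in _TABLE2:
        gene = vocab.gene_iri(g)
        info_quads.append(
            Quad(gene, fixtures.symbol_pred, LiteralValue(sym), fixtures.gene_info)
        )
        info_quads.append(Quad(gene, fixtures.taxon_pred, fixtures.human_taxon, fixtures.gene_info))

    dg = fixtures.drug_targets
    drug_quads = []
    expected: list[DrugTargetRow] = []
    for g, sym, seed_acc, _term, target_id, drugs in _TABLE2:
        gene = vocab.gene_iri(g)
        target = Iri(f"http://bio2rdf.org/drugbank_target:{target_id}")
        drug_quads.append(Quad(target, fixtures.target_gene_pred, gene, dg))
        label = _SEED_LABELS[seed_acc]
        if not drugs:
            expected.append(DrugTargetRow(gene, sym, label, target))
        for db_id, name in drugs:
            drug = Iri(f"http://bio2rdf.org/drugbank:{db_id}")
            psa = round(rng.uniform(20.0, 120.0), 1)
            drug_quads.append(Quad(drug, fixtures.drug_target_pred, target, dg))
            drug_quads.append(Quad(drug, RDFS_LABEL, LiteralValue(name), dg))
            drug_quads.append(
                Quad(drug, fixtures.psa_pred,
                     LiteralValue(repr(psa), datatype=Iri("http://www.w3.org/2001/XMLSchema#double")),
                     dg)
            )
            expected.append(DrugTargetRow(gene, sym, label, target, drug, name, psa))

    by_region = {k: () for k in _DEFAULT_WEIGHTS}
    by_region[CPG_ISLAND] = tuple(sorted(vocab.gene_iri(g).value for g, *_ in _TABLE2))
    by_region[ChromatinStateKind.POISED_PROMOTER.value] = tuple(
        sorted(vocab.gene_iri(g).value for g in _TABLE2_POISED)
    )
    truth = Truth(
        de_genes=tuple(vocab.gene_iri(g).value for g, *_ in _TABLE2),
        genes_by_region=by_region,
        expected_rows=tuple(sorted(expected, key=_row_sort_key)),
    )
    return FixtureBundle(
        de_table=de_table,
        overlap_table=tuple(overlap_rows),
        go_graph=GraphBundle(go_quads),
        annotation_graph=GraphBundle(ann_quads),
        geneinfo_graph=GraphBundle(info_quads),
        drugtarget_graph=GraphBundle(drug_quads),
        ro_manifest=default_provenance_context(),
        meta=default_publication_meta(),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# persistence and pipeline assembly

_COMPONENT_FILES = {
    "de_table": "de.tsv",
    "overlap_table": "overlap.tsv",
    "go_graph": "go.ttl",
    "annotation_graph": "annotations.ttl",
    "geneinfo_graph": "geneinfo.ttl",
    "drugtarget_graph": "drugtargets.ttl",
    "ro_manifest": "ro_manifest.json",
    "meta": "meta.yaml",
    "truth": "truth.json",
}


def write_fixture(bundle: FixtureBundle, directory: str | Path) -> None:
    """Write every component as a plain-text file (TSV/Turtle/JSON/YAML)."""
    from .context_graphs import write_ro_manifest
    from .rdf_core import write_quads

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    records_to_tsv(bundle.de_table, d / _COMPONENT_FILES["de_table"])
    records_to_tsv(bundle.overlap_table, d / _COMPONENT_FILES["overlap_table"])
    for attr in ("go_graph", "annotation_graph", "geneinfo_graph", "drugtarget_graph"):
        (d / _COMPONENT_FILES[attr]).write_text(
            write_quads(getattr(bundle, attr), "turtle"), encoding="utf-8"
        )
    write_ro_manifest(bundle.ro_manifest, d / _COMPONENT_FILES["ro_manifest"])
    meta = bundle.meta
    (d / _COMPONENT_FILES["meta"]).write_text(
        yaml.safe_dump(
            {
                "authors": [a.value for a in meta.authors],
                "contributors": [c.value for c in meta.contributors],
                "created": meta.created,
                "version": meta.version,
                "license": meta.license_iri.value,
            },
            sort_keys=False,
        ),
        encoding="utf-8",
    )
    (d / _COMPONENT_FILES["truth"]).write_text(bundle.truth.to_json() + "\n", encoding="utf-8")


def read_fixture(directory: str | Path, fixtures: FixtureGraphs | None = None) -> FixtureBundle:
    """Read a fixture directory back; missing components are named."""
    from .context_graphs import load_publication_meta, read_ro_manifest
    from .rdf_core import read_quads

    fixtures = fixtures or FixtureGraphs()
    d = Path(directory)
    if not d.is_dir():
        raise NanopubKitError(f"fixture directory {d} does not exist")
    missing = [f for f in _COMPONENT_FILES.values() if not (d / f).exists()]
    if missing:
        raise NanopubKitError(
            f"fixture directory {d} is missing component file(s): {', '.join(sorted(missing))}"
        )
    graph_iris = {
        "go_graph": fixtures.go_ontology,
        "annotation_graph": fixtures.go_annotations,
        "geneinfo_graph": fixtures.gene_info,
        "drugtarget_graph": fixtures.drug_targets,
    }
    graphs = {
        attr: read_quads(
            (d / _COMPONENT_FILES[attr]).read_text(encoding="utf-8"),
            "turtle",
            graph_iri=iri,
        )
        for attr, iri in graph_iris.items()
    }
    meta = load_publication_meta(d / _COMPONENT_FILES["meta"])
    return FixtureBundle(
        de_table=tuple(records_from_tsv(d / _COMPONENT_FILES["de_table"], "de")),
        overlap_table=tuple(records_from_tsv(d / _COMPONENT_FILES["overlap_table"], "overlap")),
        ro_manifest=read_ro_manifest(d / _COMPONENT_FILES["ro_manifest"]),
        meta=meta,
        truth=Truth.from_json((d / _COMPONENT_FILES["truth"]).read_text(encoding="utf-8")),
        **graphs,
    )


def build_store(
    bundle: FixtureBundle,
    config: RunConfig | None = None,
    vocab: VocabularyConfig | None = None,
) -> tuple[QuadStore, list[Nanopublication]]:
    """Run the publishing pipeline over a fixture bundle and load everything
    (nanopub corpus + the four fixture source graphs) into a fresh store."""
    config = config or RunConfig()
    vocab = vocab or default_vocabulary(config)
    corpus = build_corpus(
        list(bundle.de_table),
        list(bundle.overlap_table),
        vocab,
        config.policy,
        bundle.ro_manifest,
        bundle.meta,
    )
    store = QuadStore()
    store.load(corpus, source_id="nanopub-corpus")
    store.load(bundle.go_graph, source_id="go-ontology")
    store.load(bundle.annotation_graph, source_id="go-annotations")
    store.load(bundle.geneinfo_graph, source_id="gene-info")
    store.load(bundle.drugtarget_graph, source_id="drug-targets")
    return store, corpus
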