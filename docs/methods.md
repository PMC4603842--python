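# Methods

## The nanopublication model

A nanopublication is one IRI naming four RDF named graphs: a **head** that
ties the IRI to its three content graphs, an **assertion** holding the
scientific claim, a **provenance** graph describing how the claim was
produced, and a **publication-info** graph carrying citation metadata. The
package publishes two claim types from an in-silico HD study:

1. *Differential expression* — "there is a gene–disease association, linked
   with altered gene expression, that refers to gene X and Huntington's
   disease". Modelled as an association hub node: one `rdf:type` triple
   (the SIO altered-expression association class) and two `refers_to`
   spokes (the bio2rdf gene IRI; the disease class). Exactly 3 triples.
2. *Genomic overlap* — "gene Y is associated with promoter Z, and Z
   overlaps a biological region". The region branch has five variants: a
   CpG island (region typed directly; 4 triples) or a chromatin region in
   one of four states — active, weak or poised promoter, heterochromatic —
   linked by `has_state` (5 triples).

Assertions are deliberately minimal; genomic coordinates, scores and
experimental context belong in provenance, not in the claim. One
nanopublication is minted per table row (per gene for DE; per
gene–promoter–region-kind for overlaps), so a corpus of N DE rows and M
overlap rows yields N+M nanopublications.

## Identifier discipline: no blank nodes

Every node a nanopublication introduces (association hubs, promoters,
regions, the four graphs, the nanopublication itself) gets a deterministic
skolem IRI minted from a `(kind, key)` pair under a configurable base
namespace. Nanopublication keys mint directly under the base; other kinds
mint under a `kind/` segment with percent-encoded keys; the four graph
names are `#head/#assertion/#provenance/#pubinfo` fragments of the
nanopublication IRI. An alternative content-hash strategy replaces the
encoded key with its SHA-256 digest. Consequences: minting is injective
over `(kind, key)`, repeated runs are byte-identical, graph equality is
plain set equality, and no serialized document ever contains a blank-node
label. Promoter nodes are minted from `(gene, promoter_key)` and regions
from `(gene, promoter_key, region_kind)`, so one gene may carry several
promoters while repeated runs stay stable.

N-Quads output is line-sorted and is the canonical form for diffs and
determinism checks; TriG is the human-facing form; Turtle is accepted on
read for single-graph fixture ontologies.

## Vocabulary conventions (best-effort mappings)

The study this models names its vocabularies (NIFSTD, SIO, SO, bio2rdf)
without printing every term IRI. The defaults in `VocabularyConfig` and
`config.py` are therefore package conventions, all overridable via a YAML
config:

| role | default | status |
|---|---|---|
| `refers_to` | `sio:SIO_000628` ("refers to") | standard SIO id |
| DE association class | `sio:SIO_001123` | the DisGeNET convention for "gene-disease association linked with altered gene expression" |
| `associated_with`, `overlaps_with` | `obo:so#associated_with`, `obo:so#overlaps` | SO annotation-relation names |
| HD disease, promoter, CpG island | readable placeholders under the NIFSTD namespace | no printed numeric ids; override for production use |
| `biosemantics:` namespace | `http://purl.example.org/biosemantics/` | placeholder; the original namespace IRI is not public |
| nanopub→RO links | `prov:alternateOf` (entity↔RO entity), `ore:isAggregatedBy` (activity→RO) | the source figures show arrows without predicate names |

The chromatin extension itself ships as a small OWL document: six classes
with `skos:definition` annotations and one object property, `has_state`,
with domain `chromatin_region` (the only chromatin-typed class defined —
the prose says "domain chromatin" but defines no such class) and range
`chromatin_state`. One source-table cell spells "chromantin_state"; the
consistent spelling is used everywhere. Chromatin states are modelled as
classes (the region links to the state *class*), not individuals; this
keeps the extension a plain subclass hierarchy that the same closure
machinery can traverse.

## Provenance and publication info

Provenance is expressed with a fixed PROV-O allow-list (`Activity`,
`Entity`, `Agent`, `used`, `wasGeneratedBy`, `wasDerivedFrom`,
`wasAssociatedWith`, `endedAtTime`, `alternateOf`): the assertion *graph*
(never individual triples) `wasGeneratedBy` the workflow activity; the
activity `used` each input entity; outputs `wasGeneratedBy` the activity
and the assertion `wasDerivedFrom` them. Each local entity may cross-link
to its counterpart in a Research Object — the aggregation bundling the
workflow, data and execution traces — so many nanopublications can share
one provenance context and proxy the same RO without duplicating it. How
much provenance to attach is the author's decision: everything beyond the
activity–assertion link is optional. Input/output entities may carry an
optional extra type IRI for domain process-ontology classes.

Publication info puts the nanopublication IRI in subject position of every
triple: `dcterms:created` (xsd:dateTime), `dcterms:creator` per author
(researcher-id IRIs to avoid name ambiguity), `dcterms:contributor`,
`dcterms:hasVersion`, `dcterms:license`. At least one author and a license
are mandatory. When metadata is shared across a corpus, each
nanopublication still carries its own (identical) pubinfo graph.

Validation is reporting, not throwing: a `ValidationReport` lists coded
violations (exact four-statement head, four distinct graph IRIs, graph
context consistency, non-empty assertion, provenance mentioning the
assertion graph, pubinfo mentioning the nanopublication). An empty report
is equivalent to structural validity.

## GO closure and the integration query

The drug-target question — *which deregulated, epigenetically flagged
genes participate in four impaired processes and are targeted by known
drugs?* — joins five sources. Two implementation choices mirror the
two-step design the package models:

- **Materialized closure.** The seed processes and all their subclass
  descendants are computed once from the GO ontology fragment and stored
  as `(term, seed-ancestor)` pairs in a dedicated named graph, rather than
  recomputed inside the main query. The traversal treats `subClassOf` as a
  DAG and fails loudly on cycles (GO is acyclic; a cyclic fixture is a
  bug). A seed absent from the ontology is kept with no descendants, with
  a warning. Terms under two seeds yield one pair per seed.
- **URI mapping.** The ontology and the annotation source use different IRI
  schemes for the same accession (`…/obo/GO_0006914` vs `…/go:0006914`);
  closure terms are rewritten into the annotation namespace
  (accession-preserving, invertible) before storage, so the integration is
  a plain join.

The integration stages run in order: DE genes from the assertion graphs;
filter to genes with promoter-overlap nanopublications (any kind by
default, or a requested kind set with any/all semantics); join to GO
annotations through the closure; keep human-taxon genes with their
symbols; join targets and drugs. The drug join is OPTIONAL, so a target
without drugs still yields a target-level row (drug fields empty) — adding
a drug to such a target later supersedes the bare row with drug rows;
gene/target associations and drug-level rows are never lost. Each stage is
an individually callable function backed by a canned SPARQL file under
`nanopubkit/queries/`; a single composed query over all five sources is
the cross-check and must return identical rows.

PSA (polar surface area, Å²) prioritization keeps rows with PSA strictly
below the threshold (default 60, the blood–brain-barrier rule of thumb);
rows without a PSA are warned about and kept or dropped per policy.

The fixture-side predicates (`goa_vocabulary:go-term`,
`geneid_vocabulary:symbol`/`taxid`, `drugbank_vocabulary:gene`/`target`/
`psa`) are artifact-defined: the original sources' exact predicate
vocabulary is not fully recoverable, so the query templates are
parameterized by predicate IRI and documented here rather than presented
as source facts.

## Synthetic data: what it emulates, and what it does not

`generate(FixtureSpec)` emulates the *shape* of the study's result tables
and of the knowledge sources they were joined with — not the underlying
biology. Defaults (chosen once as a realistic desk-scale study):
200 genes; 50% differentially expressed; overlap rows only for DE genes
(the upstream workflow filtered on DE), 1–2 region kinds per gene drawn
from uniform weights over the five kinds; a GO DAG of depth 3 and
branching 2 under each of the four seeds plus an off-seed subtree, with
occasional within-subtree diamonds; 60% of genes annotated under seeds;
90% human taxon; 80% of genes with a drug target; 0–3 drugs per target;
PSA uniform on 20–120 Å². Synthetic gene ids start at 10⁹ to stay clear of
real NCBI ids; synthetic GO accessions use the 9xxxxxx range.

The generator records **truth** during construction — the DE gene set, the
genes per region kind, and the exact expected integration rows — so the
end-to-end test compares pipeline output against an answer that never
touched the query engine. What passing these tests shows: the templates,
assembly, serialization, closure and joins are lossless and correct on
data of this shape. What they do not show: anything about real microarray
noise, real GO topology at full scale, real DrugBank coverage, or the
biological validity of the associations; expression values, normalization
and genomic coordinates are not simulated at all.

The packaged worked example (`table2_fixture`) pins the published result
set: eight genes, six drug-bearing or drug-less targets, twelve drugs.
ABL1 is annotated to macroautophagy (GO:0016236 ⊑ autophagy) so the
example genuinely exercises the closure; PPIA/PPIB/PPIC are
protein-folding-annotated with targets but no drugs, matching their blank
table cells. Its PSA values are synthetic (deterministic, clearly
labelled): none are published.

## Numerical and operational choices

- Determinism everywhere: one integer seed drives each generator
  (`random.Random(seed)`); timestamps in fixtures are fixed constants;
  N-Quads are sorted before writing. Equal seeds give byte-identical
  files.
- Simple literals and `xsd:string` literals are identified (RDF 1.1), so
  round trips are exact under set equality.
- Degenerate inputs: an empty DE table is valid and yields an empty corpus
  and empty query answers; an empty region-kind set for the all-mode
  filter would be a vacuous conjunction and is rejected instead; a
  three-graph document read as a nanopublication is a structure error, not
  a partial object.
- Problem sizes in the test-suite and acceptance runs — a ~1,000
  nanopublication corpus, 100 random DAGs of ≤200 nodes for the closure
  oracle, studies of 50/200/1,000 genes — are the package's chosen
  desk-scale study conditions; the full-scale published analysis (live
  bio2rdf/DrugBank endpoints, complete GO) is explicitly out of scope.

## Known limitations

- No OWL reasoning or consistency checking; subclass traversal is the only
  inference performed.
- No trusty/content-hash nanopublication URIs by default (the content-hash
  minting strategy exists but is off), and no publishing to a public
  nanopublication server network.
- The vocabulary defaults marked best-effort above must be overridden with
  curated IRIs before publishing outside a sandbox.
- RDF lists and blank nodes are unsupported by design; foreign documents
  containing blank nodes are rejected on read.
- The composed integration query covers the default any-region filter
  only; kind-restricted filters run through the staged path.
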