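# nanopubkit

Expose the results of a transcriptomics/epigenomics analysis as
**nanopublications** — the smallest publishable units of data: one RDF
assertion packaged with provenance and publication-info metadata as named
graphs — and integrate them with linked-data knowledge sources.

The package is built around a Huntington's disease (HD) use case: genes
found deregulated in the HD caudate nucleus, and the overlap of their
promoters with epigenetic features (CpG islands and chromatin states). It
is aimed at computational biologists and data publishers who want their
result tables to be findable, citable and queryable rather than buried in
supplements.

## What it implements

**Two assertion templates.** A differential-expression assertion — an
association node typed with the SIO class for a gene–disease association
linked with altered gene expression, with two `refers_to` spokes:

```
:assoc  rdf:type   sio:gene-disease-association-with-altered-expression .
:assoc  refers_to  bio2rdf:geneid:X .
:assoc  refers_to  nifstd:HuntingtonsDisease .
```

and a genomic-overlap assertion — `gene associated_with promoter`,
`promoter overlaps_with region`, where the region is a CpG island or a
chromatin region carrying one of four states (active/weak/poised promoter,
heterochromatic) via `has_state`, giving five structurally distinct
nanopublication variants. Assertions are kept minimal (3–5 triples); all
context lives in the other graphs.

**A Sequence Ontology extension** for the chromatin vocabulary: six classes
(`chromatin_region` ⊑ SO:0001411 *biological_region*, `chromatin_state` ⊑
SO:0000733 *feature_attribute*, and the four states ⊑ `chromatin_state`)
plus the `has_state` object property.

**Context graphs.** PROV-O provenance (the workflow activity that
`wasGeneratedBy`/`used`/`wasDerivedFrom` ties to the assertion graph), with
optional cross-links into a Research Object so the nanopublication acts as
a lightweight proxy for the full workflow pack; and publication info
(ORCID-style authors, timestamp, version, license) about the
nanopublication IRI itself.

**Assembly, validation, serialization.** Head + assertion + provenance +
pubinfo under one IRI with `#fragment` graph names; structural validation
with machine-readable violation codes; deterministic TriG and line-sorted
N-Quads (no blank nodes anywhere — every internal node is a skolem IRI
minted from a `(kind, key)` pair).

**Store and queries.** A local quad store with canned SPARQL queries
(DE genes; genes by region kind, any/all), materialization of the GO
subclass closure beneath four seed processes — proteasomal protein
catabolic process (GO:0010498), autophagy (GO:0006914), protein folding
(GO:0006457), protein unfolding (GO:0043335) — with accession-preserving
URI mapping between the ontology and annotation namespaces, and a
five-source drug-target integration (nanopubs → GO annotation → human gene
info → DrugBank-style targets/drugs), with a PSA < 60 Å² filter for
blood–brain-barrier candidates. The integration runs staged or as one
composed query; both must agree.

**Synthetic data.** A seeded generator for every input (result tables, toy
GO DAG, annotation/gene-info/drug-target graphs, RO manifest, metadata)
with *truth bookkeeping*, plus a packaged worked example of eight
HD genes, their targets and drugs.

## Worked example

```bash
python examples/worked_example_drug_targets.py
```

prints the integration result (abridged):

```
Gene                          GeneSymbol  GoTerm      Target             Drug     DrugDescription
http://bio2rdf.org/geneid:25  ABL1        autophagy   …drugbank_target:17  …DB00619  Imatinib
http://bio2rdf.org/geneid:25  ABL1        autophagy   …drugbank_target:17  …DB01254  Dasatinib
…
rows with synthetic PSA < 60 Å² (candidate brain-permeable drugs): 6 of 15
  ABL1     Imatinib     PSA=22.5
  ABL1     Dasatinib    PSA=47.5
```

Each row joins a deregulated gene (published as a nanopublication) through
its promoter-overlap nanopublications and GO annotation to a drug target:
ABL1 reaches the autophagy seed only through the subclass closure
(macroautophagy ⊑ autophagy), and drug-less targets (PPIA/PPIB/PPIC)
appear at target level only. PSA values are synthetic illustration values;
the strict `< 60` cut mirrors the blood–brain-barrier permeability rule of
thumb.

The other scripts under `examples/` each demonstrate one capability
(corpus building and validation, the ontology extension, closure mapping,
the end-to-end synthetic pipeline).

There is also a CLI:

```bash
nanopubkit fixtures table2 -o fx
nanopubkit build --de fx/de.tsv --overlap fx/overlap.tsv \
    --prov fx/ro_manifest.json --meta fx/meta.yaml -o corpus.trig
nanopubkit validate corpus.trig
nanopubkit integrate --fixture-dir fx -o results.tsv
nanopubkit psa-filter results.tsv --max 60
```

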