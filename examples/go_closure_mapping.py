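"""Materialize a GO subclass closure with cross-namespace URI mapping.

The ontology uses OBO-style IRIs (…/obo/GO_0006914) while the annotation
source uses bio2rdf-style ones (…/go:0006914); the closure rewrites every
descendant into the annotation namespace before storing it, so the
integration query is a plain join.
"""

from nanopubkit import GraphBundle, Iri, Quad, QuadStore, materialize_go_closure
from nanopubkit.config import RDFS_SUBCLASSOF
from nanopubkit.store_query import GoSeedConfig

OBO = "http://purl.obolibrary.org/obo/GO_{}"
graph = Iri("urn:x-fixture:go-ontology")
edges = [  # autophagy with two children and one grandchild
    ("0016236", "0006914"),
    ("0061919", "0006914"),
    ("0016237", "0016236"),
]
bundle = GraphBundle(
    Quad(Iri(OBO.format(c)), RDFS_SUBCLASSOF, Iri(OBO.format(p)), graph)
    for c, p in edges
)
store = QuadStore().load(bundle, source_id="go")
seeds = GoSeedConfig(seeds=("GO:0006914",))
closure = materialize_go_closure(store, seeds=seeds)

for q in sorted(closure.quads, key=lambda q: q.subject.value):
    if q.predicate == seeds.closure_predicate:
        print(f"{q.subject.value}  ->  seed {q.object.value}")
# Expected: four bio2rdf-namespace terms (the seed, both children, the
# grandchild), each paired with the seed — a gene annotated to any of them
# counts as hitting autophagy.
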