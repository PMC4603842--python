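# Every subclass descendant (reflexive, transitive) of one seed GO term
# inside the GO ontology fixture graph.
SELECT DISTINCT ?term WHERE {
  GRAPH <$ontology_graph> {
    ?term <http://www.w3.org/2000/01/rdf-schema#subClassOf>* <$seed> .
  }
}
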