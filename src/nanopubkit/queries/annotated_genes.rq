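# Genes annotated to any GO term that the materialized closure graph maps
# to a seed ancestor; returns the seed (annotation-namespace IRI) as well.
SELECT DISTINCT ?gene ?seed WHERE {
  GRAPH <$annotation_graph> { ?gene <$go_term_pred> ?term . }
  GRAPH <$closure_graph>    { ?term <$closure_pred> ?seed . }
}
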