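# Gene symbols restricted to the human taxon.
SELECT DISTINCT ?gene ?symbol WHERE {
  GRAPH <$geneinfo_graph> {
    ?gene <$symbol_pred> ?symbol ;
          <$taxon_pred> <$human_taxon> .
  }
}
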