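# The five-source drug-target integration as one query.  Sections, in the
# staged order: (1) differentially expressed genes from the nanopublication
# assertions, (2) the promoter/region overlap filter, (3) GO annotation
# joined through the materialized seed closure, (4) human-taxon gene info,
# (5) DrugBank-style targets and drugs (drug join optional, so drug-less
# targets survive at target level).
SELECT DISTINCT ?gene ?symbol ?seed ?golabel ?target ?drug ?drugname ?psa WHERE {
  # 1 - differential expression nanopublications
  GRAPH ?ag {
    ?assoc a <$assoc_class> ;
           <$refers_to> ?gene .
  }
  FILTER(?gene != <$disease>)

  # 2 - genomic-overlap nanopublications
  ?gene <$associated_with> ?promoter .
  ?promoter <$overlaps_with> ?region .

  # 3 - GO annotation via the materialized closure
  GRAPH <$annotation_graph> { ?gene <$go_term_pred> ?term . }
  GRAPH <$closure_graph>    {
    ?term <$closure_pred> ?seed .
    OPTIONAL { ?seed <http://www.w3.org/2000/01/rdf-schema#label> ?golabel }
  }

  # 4 - human gene info
  GRAPH <$geneinfo_graph> {
    ?gene <$symbol_pred> ?symbol ;
          <$taxon_pred> <$human_taxon> .
  }

  # 5 - drug targets and drugs
  GRAPH <$drugtarget_graph> {
    ?target <$target_gene_pred> ?gene .
    OPTIONAL {
      ?drug <$drug_target_pred> ?target .
      OPTIONAL { ?drug <http://www.w3.org/2000/01/rdf-schema#label> ?drugname }
      OPTIONAL { ?drug <$psa_pred> ?psa }
    }
  }
}
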