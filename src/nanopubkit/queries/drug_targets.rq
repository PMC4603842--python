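# Drug targets for a gene, with the drugs aimed at each target (targets
# without a drug still appear: the drug join is optional).
SELECT DISTINCT ?gene ?target ?drug ?drugname ?psa WHERE {
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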