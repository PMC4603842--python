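# All genes asserted as differentially expressed: every assertion graph
# holds an association node typed with the altered-expression association
# class, pointing at the gene and at the disease via refers_to.
SELECT DISTINCT ?gene WHERE {
  GRAPH ?g {
    ?assoc a <$assoc_class> ;
           <$refers_to> ?gene .
  }
  FILTER(?gene != <$disease>)
}
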