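# Genes whose promoter overlaps a CpG island.
SELECT DISTINCT ?gene WHERE {
  ?gene <$associated_with> ?promoter .
  ?promoter <$overlaps_with> ?region .
  ?region a <$cpg_class> .
}
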