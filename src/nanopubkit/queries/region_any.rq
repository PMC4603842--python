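# Genes having at least one promoter-overlap assertion of any region kind.
SELECT DISTINCT ?gene WHERE {
  ?gene <$associated_with> ?promoter .
  ?promoter <$overlaps_with> ?region .
}
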