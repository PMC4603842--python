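"""The packaged worked example: drug-target prioritization.

Loads the worked-example fixture (eight HD-deregulated genes with their
overlap nanopublications, a GO fragment, annotations, gene info and
DrugBank-like targets), materializes the subclass closure of the four seed
biological processes, runs the five-source integration and applies the
PSA < 60 Å² blood–brain-barrier filter.
"""

import warnings

from nanopubkit import filter_psa, integrate_drug_targets
from nanopubkit.store_query import rows_to_tsv
from nanopubkit.synthetic_data import build_store, table2_fixture

store, corpus = build_store(table2_fixture())
print(f"loaded {len(corpus)} nanopublications and 4 fixture graphs "
      f"({len(store)} quads)\n")

rows = integrate_drug_targets(store)
print(rows_to_tsv(rows))
# Each row: gene, symbol, seed GO process, DrugBank target, drug.  ABL1
# resolves through macroautophagy -> autophagy, i.e. via the closure, not a
# direct annotation.  PPIA/PPIB/PPIC have targets but no drugs, so they
# appear only at target level.

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # drug-less rows carry no PSA
    permeable = filter_psa(rows, threshold=60.0, missing="drop")
print(f"rows with synthetic PSA < 60 Å² (candidate brain-permeable drugs): "
      f"{len(permeable)} of {len(rows)}")
for r in permeable:
    print(f"  {r.gene_symbol:8s} {r.drug_name:12s} PSA={r.psa}")
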