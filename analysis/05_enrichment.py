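"""Hypergeometric gene-set enrichment of the selected responders.

Every gene set is intersected with the array universe, tested with the
one-sided hypergeometric upper tail, BH-adjusted across the merged family,
and called significant when -log10(p) > 1.3 (p < 0.05).
"""

import json
from pathlib import Path

import pandas as pd

from trainmap import enrich
from trainmap.io_formats import read_gmt

RESULTS = Path(__file__).resolve().parent.parent / "results"

results = pd.read_csv(RESULTS / "differential.tsv", sep="\t", index_col="gene")
results.index = results.index.astype(str)
responders = list(results.index[results["selected"]])
universe = list(results.index)

truth = json.loads((RESULTS / "data" / "truth.json").read_text())
collection = None
for tag in "KGPR":
    path = RESULTS / "data" / f"gene_sets_{tag}.gmt"
    if not path.exists():
        continue
    part = read_gmt(path, tag)
    collection = part if collection is None else collection.merge(part)

table = enrich(responders, universe, collection)
table.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)

sig = table[table["significant"]]
planted_sig = sig[sig["set"].isin(truth["planted_sets"])]
print(f"{len(sig)} / {len(table)} sets significant (-log10 p > 1.3)")
print(f"planted sets recovered: {len(planted_sig)} / {len(truth['planted_sets'])}")
print(planted_sig[["set", "K", "k", "p", "score"]].to_string(index=False))
print(f"wrote {RESULTS}/enrichment.tsv")
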