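"""Draw the synthetic two-stimulus training experiment.

Writes the expression matrix, annotation sidecar, merged gene-set GMT and
the ground-truth JSON under results/data/.  The defaults are the study
conditions: 5,000 genes, 200 responders (trainer effect 2.0 vs comparator
0.5 log2 units), noise sd 0.5, triplicates, three planted 30-gene sets at
80% responder purity and 100 decoys.
"""

import dataclasses
import json
from pathlib import Path

from trainmap import SimulationConfig, simulate
from trainmap.io_formats import write_expression, write_gmt

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

config = SimulationConfig(seed=1)
matrix, collection, truth = simulate(config)

OUT.mkdir(parents=True, exist_ok=True)
write_expression(matrix, OUT / "expression.tsv", OUT / "annotations.tsv")
# one GMT per source tag, the same shape real K/G/P/R collections arrive in
from trainmap.io_formats import GeneSetCollection

tags = sorted({gs.source for gs in collection})
for tag in tags:
    part = GeneSetCollection({k: gs for k, gs in collection.sets.items()
                              if gs.source == tag})
    write_gmt(part, OUT / f"gene_sets_{tag}.gmt")
truth.to_json(OUT / "truth.json")
(OUT / "sim_config.json").write_text(
    json.dumps(dataclasses.asdict(config), indent=1) + "\n"
)

print(f"simulated {len(matrix.gene_ids)} genes x {len(matrix.sample_ids)} samples")
print(f"{len(truth.responders)} responder genes, "
      f"{len(truth.planted_sets)} planted sets, {len(truth.decoy_sets)} decoys")
print(f"wrote {OUT}/expression.tsv, annotations.tsv, "
      f"gene_sets_{{{','.join(tags)}}}.gmt, truth.json")
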