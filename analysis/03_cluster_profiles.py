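"""K-means clustering of gene response profiles.

Each gene's profile is (snr_trainer, snr_comparator, response_trainer,
response_comparator), standardized per dimension; the resulting clusters
scope the per-gene factorial tests.
"""

from pathlib import Path

from trainmap import cluster_profiles, make_profiles, response_summary
from trainmap.io_formats import read_expression

RESULTS = Path(__file__).resolve().parent.parent / "results"

matrix = read_expression(RESULTS / "normalized.tsv",
                         RESULTS / "data" / "annotations.tsv")
summary = response_summary(matrix)
summary.to_csv(RESULTS / "response_summary.tsv", sep="\t", index_label="gene")

profiles = make_profiles(summary)
assignment = cluster_profiles(profiles, k=9, seed=17, restarts=10)
assignment.labels.to_frame().to_csv(RESULTS / "clusters.tsv", sep="\t",
                                    index_label="gene")

print(f"k={assignment.k} clusters, WCSS={assignment.wcss:.1f}")
print("cluster sizes:", assignment.sizes().to_dict())
print(f"wrote {RESULTS}/response_summary.tsv and clusters.tsv")
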