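"""End-to-end orchestration: matrix -> normalized -> clusters -> responders
-> enrichment -> map.

`run_pipeline` takes any annotated expression matrix plus a merged gene-set
collection; `run_synthetic` first draws a synthetic experiment and then runs
the same pipeline, returning the ground truth alongside, which is how the
planted-recovery studies are executed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import clustering, differential, emap, enrichment, preprocess
from .io_formats import ExpressionMatrix, GeneSetCollection
from .synthetic_data import GroundTruth, SimulationConfig, simulate


@dataclass
class PipelineResult:
    normalized: ExpressionMatrix
    summary: pd.DataFrame
    clusters: clustering.ClusterAssignment
    differential: pd.DataFrame
    responders: list[str]
    enrichment: pd.DataFrame
    emap: emap.EnrichmentMap


def run_pipeline(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    k: int = clustering.DEFAULT_K,
    cluster_seed: int = clustering.DEFAULT_SEED,
    restarts: int = clustering.DEFAULT_RESTARTS,
    alpha: float = differential.DEFAULT_ALPHA,
    per_cluster_bh: bool = True,
    score_threshold: float = enrichment.SCORE_THRESHOLD,
    min_set_size: int = enrichment.MIN_SET_SIZE,
    max_set_size: int = enrichment.MAX_SET_SIZE,
    use_adjusted: bool = False,
    edge_threshold: float = emap.DEFAULT_EDGE_THRESHOLD,
) -> PipelineResult:
    normalized = preprocess.quantile_normalize(matrix)
    summary = preprocess.response_summary(normalized)
    profiles = clustering.make_profiles(summary)
    clusters = clustering.cluster_profiles(
        profiles, k=k, seed=cluster_seed, restarts=restarts
    )
    diff = differential.run_differential(
        normalized, clusters.labels, alpha=alpha, per_cluster=per_cluster_bh
    )
    responders = list(diff.index[diff["selected"]])
    universe = normalized.gene_ids
    enr = enrichment.enrich(
        responders,
        universe,
        collection,
        score_threshold=score_threshold,
        min_set_size=min_set_size,
        max_set_size=max_set_size,
        use_adjusted=use_adjusted,
    )
    the_map = emap.build_map(enr, collection, universe, edge_threshold=edge_threshold)
    return PipelineResult(
        normalized=normalized,
        summary=summary,
        clusters=clusters,
        differential=diff,
        responders=responders,
        enrichment=enr,
        emap=the_map,
    )


def run_synthetic(
    config: SimulationConfig, **pipeline_kwargs
) -> tuple[PipelineResult, GroundTruth]:
    matrix, collection, truth = simulate(config)
    result = run_pipeline(matrix, collection, **pipeline_kwargs)
    return result, truth
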