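"""Synthetic two-stimulus expression data with planted ground truth.

The generator emulates the factorial monocyte-training design: a trainer
stimulus (beta-glucan) and a comparator stimulus (LPS), each measured at
baseline and after stimulation.  A chosen subset of *responder* genes gains
``trainer_effect`` log2 units under (trainer, stimulated) and the smaller
``comparator_effect`` under (comparator, stimulated); every other gene is
flat.  Each gene has its own baseline abundance, drawn once from
N(baseline_mean, baseline_sd) — arrays span several log2 units of
between-gene abundance, and that spread is what makes quantile
normalization effect-preserving — and all cells receive i.i.d. Gaussian
noise on top.  Planted gene sets are concentrated in the responders (a
``planted_purity`` fraction of their members), decoy sets are drawn uniformly
from all genes; together they give every downstream stage a known truth.

One global RNG stream is consumed in a documented order — gene-level
quantities first (responder identity, baselines, noise), then set-level
quantities (planted members, decoy members) — so identical seeds give
identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SOURCE_TAGS,
    STATES,
    STIMULI,
)

BASELINE_MEAN_LOG2 = 8.0
BASELINE_SD_LOG2 = 2.0


class ConfigError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic training-response experiment.

    Defaults mirror a realistic array-scale experiment: 5,000 genes of which
    200 respond with a strong trainer effect (2.0 log2 units) and a weak
    comparator effect (0.5), per-gene baselines of 8.0 +/- 2.0 log2 units,
    Gaussian noise of 0.5 log2 units, triplicates per (stimulus, state)
    cell, three planted 30-gene sets at 80% responder purity and 100 decoy
    sets.
    """

    n_genes: int = 5000
    n_responders: int = 200
    trainer_effect: float = 2.0
    comparator_effect: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = BASELINE_MEAN_LOG2
    baseline_sd: float = BASELINE_SD_LOG2
    replicates: int = 3
    n_planted_sets: int = 3
    n_decoy_sets: int = 100
    planted_set_size: int = 30
    planted_purity: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_responders < 0 or self.n_responders > self.n_genes:
            raise ConfigError("n_responders must lie in [0, n_genes]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.baseline_sd < 0:
            raise ConfigError("baseline_sd must be non-negative")
        if self.replicates < 2:
            raise ConfigError("need at least 2 replicates per cell")
        if self.comparator_effect >= self.trainer_effect:
            raise ConfigError("comparator_effect must be < trainer_effect")
        if self.planted_set_size <= 0 or self.planted_set_size > self.n_genes:
            raise ConfigError("planted_set_size must lie in [1, n_genes]")
        if not (0 < self.planted_purity <= 1):
            raise ConfigError("planted_purity must lie in (0, 1]")
        if self.n_planted_sets < 0 or self.n_decoy_sets < 0:
            raise ConfigError("set counts must be non-negative")
        n_pure = round(self.planted_purity * self.planted_set_size)
        if self.n_planted_sets > 0 and n_pure > self.n_responders:
            raise ConfigError(
                "planted_purity * planted_set_size exceeds n_responders"
            )


@dataclass
class GroundTruth:
    responders: list[str] = field(default_factory=list)
    planted_sets: list[str] = field(default_factory=list)
    decoy_sets: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, GeneSetCollection, GroundTruth]:
    """Draw one synthetic experiment: matrix, gene sets and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    gene_arr = np.array(genes)

    # genes first: responder identity, per-gene baselines, then the noise field
    responder_idx = rng.choice(config.n_genes, size=config.n_responders, replace=False)
    responder_mask = np.zeros(config.n_genes, dtype=bool)
    responder_mask[responder_idx] = True
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)

    sample_ids, stim_col, state_col, rep_col = [], [], [], []
    for stimulus in STIMULI:
        for state in STATES:
            for rep in range(1, config.replicates + 1):
                sample_ids.append(f"{stimulus}_{state}_r{rep}")
                stim_col.append(stimulus)
                state_col.append(state)
                rep_col.append(rep)
    annotations = pd.DataFrame(
        {"stimulus": stim_col, "state": state_col, "replicate": rep_col},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    n_samples = len(sample_ids)
    signal = np.tile(baselines[:, None], (1, n_samples))
    for j, sid in enumerate(sample_ids):
        if state_col[j] != "stimulated":
            continue
        effect = (
            config.trainer_effect if stim_col[j] == "trainer"
            else config.comparator_effect
        )
        signal[responder_mask, j] += effect
    noise = rng.normal(0.0, config.noise_sd, size=signal.shape)
    values = pd.DataFrame(signal + noise, index=genes, columns=sample_ids)
    matrix = ExpressionMatrix(values=values, annotations=annotations)

    # sets second: planted then decoys
    collection = GeneSetCollection()
    truth = GroundTruth(responders=sorted(gene_arr[responder_mask].tolist()))
    non_responders = np.flatnonzero(~responder_mask)
    n_pure = round(config.planted_purity * config.planted_set_size)
    n_impure = config.planted_set_size - n_pure
    for i in range(config.n_planted_sets):
        pure = rng.choice(responder_idx, size=n_pure, replace=False)
        impure = rng.choice(non_responders, size=n_impure, replace=False)
        members = frozenset(gene_arr[np.concatenate([pure, impure])])
        gs = GeneSet(
            name=f"PLANTED_{i + 1:02d}",
            source=SOURCE_TAGS[i % len(SOURCE_TAGS)],
            description="planted responder-enriched set",
            members=members,
        )
        collection.add(gs)
        truth.planted_sets.append(gs.qualified_name)
    for i in range(config.n_decoy_sets):
        idx = rng.choice(config.n_genes, size=config.planted_set_size, replace=False)
        gs = GeneSet(
            name=f"DECOY_{i + 1:03d}",
            source=SOURCE_TAGS[i % len(SOURCE_TAGS)],
            description="decoy set drawn uniformly from all genes",
            members=frozenset(gene_arr[idx]),
        )
        collection.add(gs)
        truth.decoy_sets.append(gs.qualified_name)
    return matrix, collection, truth
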