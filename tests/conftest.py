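import numpy as np
import pandas as pd
import pytest

from trainmap.io_formats import ExpressionMatrix, GeneSet, GeneSetCollection


def make_annotations(replicates: int = 2) -> pd.DataFrame:
    rows = []
    for stimulus in ("trainer", "comparator"):
        for state in ("baseline", "stimulated"):
            for rep in range(1, replicates + 1):
                rows.append((f"{stimulus}_{state}_r{rep}", stimulus, state, rep))
    ann = pd.DataFrame(rows, columns=["sample_id", "stimulus", "state", "replicate"])
    return ann.set_index("sample_id")


def make_matrix(values: np.ndarray, genes=None, replicates: int = 2) -> ExpressionMatrix:
    """Wrap a genes x (4*replicates) array in an annotated ExpressionMatrix."""
    ann = make_annotations(replicates)
    values = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"G{i:03d}" for i in range(1, values.shape[0] + 1)]
    frame = pd.DataFrame(values, index=genes, columns=ann.index)
    return ExpressionMatrix(values=frame, annotations=ann)


def cell_means_matrix(cell_means: dict, noise_sd: float, n_genes: int,
                      replicates: int, rng) -> ExpressionMatrix:
    """Matrix whose (stimulus, state) cells have the given means plus noise.

    cell_means maps (stimulus, state) -> mean expression for every gene.
    """
    ann = make_annotations(replicates)
    cols = []
    for sid in ann.index:
        stim, state = ann.loc[sid, "stimulus"], ann.loc[sid, "state"]
        mean = cell_means[(stim, state)]
        cols.append(mean + rng.normal(0.0, noise_sd, n_genes))
    values = np.column_stack(cols)
    return make_matrix(values, replicates=replicates)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    return make_matrix(8.0 + rng.normal(0, 1, size=(6, 8)))


@pytest.fixture
def small_collection() -> GeneSetCollection:
    coll = GeneSetCollection()
    coll.add(GeneSet("UBIQUITIN", "G", "ubiquitin catabolism",
                     frozenset({"G001", "G002", "G003"})))
    coll.add(GeneSet("GLYCOLYSIS", "K", "glycolysis pathway",
                     frozenset({"G004", "G005"})))
    return coll
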