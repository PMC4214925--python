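"""Quantile normalization and per-gene response summaries.

Array columns are forced onto a common value distribution by rank-wise
means, the standard microarray quantile normalization.  Each gene's response
to a stimulus is summarized as the stimulated-minus-baseline mean difference
(log2 units) and as a signal:noise ratio in the GSEA sense,
(mu_stimulated - mu_baseline) / (sd_stimulated + sd_baseline), the
standardized measure shown as heatmaps in response-profile analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix

SD_FLOOR = 1e-8


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common rank-mean distribution.

    The reference distribution is the vector of row-wise means of the
    rank-sorted columns.  Ties within a column receive the mean of the
    reference values spanning their rank positions, which makes the
    operation order-independent and idempotent.
    """
    x = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    # average ranks are 1-based; a tie group with average rank r and g members
    # spans reference positions r-(g-1)/2 ... r+(g-1)/2
    ref_cumsum = np.concatenate([[0.0], np.cumsum(reference)])
    for j in range(n_samples):
        ranks = rankdata(x[:, j], method="average")
        lo = np.rint(ranks - _tie_halfwidth(x[:, j])).astype(int)
        hi = np.rint(ranks + _tie_halfwidth(x[:, j])).astype(int)
        out[:, j] = (ref_cumsum[hi] - ref_cumsum[lo - 1]) / (hi - lo + 1)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(values)


def _tie_halfwidth(col: np.ndarray) -> np.ndarray:
    """(group size - 1) / 2 for each value's tie group within the column."""
    _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
    return (counts[inverse] - 1) / 2.0


def signal_to_noise(
    matrix: ExpressionMatrix,
    stimulus: str,
    versus: str = "baseline",
) -> pd.Series:
    """Per-gene signal:noise ratio of a stimulus response.

    By default the contrast is (stimulus, stimulated) against
    (stimulus, baseline); ``versus="other"`` contrasts the stimulated states
    of the two stimuli instead.  Sample standard deviations use the n-1
    denominator and their sum is floored at 1e-8.
    """
    if versus == "baseline":
        top = matrix.samples_in(stimulus, "stimulated")
        bottom = matrix.samples_in(stimulus, "baseline")
    elif versus == "other":
        other = "comparator" if stimulus == "trainer" else "trainer"
        top = matrix.samples_in(stimulus, "stimulated")
        bottom = matrix.samples_in(other, "stimulated")
    else:
        raise ValueError(f"versus must be 'baseline' or 'other', got {versus!r}")
    for name, group in (("stimulated", top), ("reference", bottom)):
        if len(group) < 2:
            raise ValueError(
                f"signal:noise for stimulus {stimulus!r} needs >=2 replicates "
                f"in the {name} group, found {len(group)}"
            )
    a = matrix.values[top].to_numpy(dtype=float)
    b = matrix.values[bottom].to_numpy(dtype=float)
    delta = a.mean(axis=1) - b.mean(axis=1)
    spread = a.std(axis=1, ddof=1) + b.std(axis=1, ddof=1)
    snr = delta / np.maximum(spread, SD_FLOOR)
    return pd.Series(snr, index=matrix.values.index, name=f"snr_{stimulus}")


def response(matrix: ExpressionMatrix, stimulus: str) -> pd.Series:
    """Per-gene mean(stimulated) - mean(baseline) for one stimulus, log2 units."""
    top = matrix.samples_in(stimulus, "stimulated")
    bottom = matrix.samples_in(stimulus, "baseline")
    r = (
        matrix.values[top].mean(axis=1) - matrix.values[bottom].mean(axis=1)
    )
    r.name = f"response_{stimulus}"
    return r


def response_summary(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Response and signal:noise for both stimuli, one row per gene."""
    return pd.DataFrame(
        {
            "snr_trainer": signal_to_noise(matrix, "trainer"),
            "snr_comparator": signal_to_noise(matrix, "comparator"),
            "response_trainer": response(matrix, "trainer"),
            "response_comparator": response(matrix, "comparator"),
        }
    )
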