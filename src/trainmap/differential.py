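"""Per-gene factorial testing for stimulus-dependent responses.

Each gene is fit with the two-factor fixed-effects model

    value = mu + a*[stimulated] + b*[trainer] + c*[stimulated x trainer] + eps

so that ``a`` is the comparator (LPS) response, ``a + c`` the trainer
(beta-glucan) response, and the interaction ``c`` is exactly the difference
between the two responses.  Significance of ``c`` is the partial F-test of
the full model against the additive one, with n - 4 residual degrees of
freedom.  P-values are Benjamini-Hochberg adjusted within each K-means
cluster (optionally globally) and genes with adjusted p below alpha *and* a
positive interaction — a stronger trainer than comparator response — are
selected as responders.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
_ZERO_RSS_TOL = 1e-12

RESULT_COLUMNS = (
    "gene",
    "cluster",
    "beta_trainer",
    "beta_comparator",
    "interaction_estimate",
    "F",
    "p_interaction",
    "p_adjusted",
    "selected",
)


def _design(annotations: pd.DataFrame, sample_ids) -> tuple[np.ndarray, np.ndarray]:
    """Full (n x 4) and additive (n x 3) design matrices in sample order."""
    ann = annotations.loc[list(sample_ids)]
    stimulated = (ann["state"] == "stimulated").to_numpy(dtype=float)
    trainer = (ann["stimulus"] == "trainer").to_numpy(dtype=float)
    x_full = np.column_stack(
        [np.ones_like(stimulated), stimulated, trainer, stimulated * trainer]
    )
    return x_full, x_full[:, :3]


def _check_cells(matrix: ExpressionMatrix) -> None:
    for stimulus in ("trainer", "comparator"):
        for state in ("baseline", "stimulated"):
            n = len(matrix.samples_in(stimulus, state))
            if n < 2:
                raise ValueError(
                    f"cell ({stimulus}, {state}) has {n} replicates; "
                    "the factorial test needs at least 2 per cell"
                )


def factorial_test_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Interaction F-test for every gene at once.

    The design matrix is shared across genes, so the OLS fits reduce to two
    matrix products; returns a DataFrame indexed by gene with columns
    beta_trainer, beta_comparator, interaction_estimate, F, p_interaction.
    """
    _check_cells(matrix)
    y = matrix.values.to_numpy(dtype=float)  # genes x samples
    x_full, x_add = _design(matrix.annotations, matrix.sample_ids)
    n = x_full.shape[0]
    df_resid = n - 4

    beta = y @ np.linalg.pinv(x_full).T  # genes x 4
    rss_full = ((y - beta @ x_full.T) ** 2).sum(axis=1)
    beta_add = y @ np.linalg.pinv(x_add).T
    rss_add = ((y - beta_add @ x_add.T) ** 2).sum(axis=1)

    a = beta[:, 1]  # comparator response
    c = beta[:, 3]  # interaction: trainer minus comparator response

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (rss_add - rss_full) / (rss_full / df_resid)
    p = stats.f.sf(f_stat, 1, df_resid)

    degenerate = rss_full <= _ZERO_RSS_TOL
    if degenerate.any():
        logger.warning(
            "%d genes have zero residual variance; p set to 0 where the "
            "interaction estimate is nonzero, 1 where it is zero",
            int(degenerate.sum()),
        )
        zero_c = np.abs(c) <= _ZERO_RSS_TOL
        p = np.where(degenerate, np.where(zero_c, 1.0, 0.0), p)
        f_stat = np.where(degenerate, np.where(zero_c, 0.0, np.inf), f_stat)

    return pd.DataFrame(
        {
            "beta_trainer": a + c,
            "beta_comparator": a,
            "interaction_estimate": c,
            "F": f_stat,
            "p_interaction": p,
        },
        index=matrix.values.index,
    )


def factorial_test(
    values: pd.Series, annotations: pd.DataFrame
) -> tuple[float, float, float, float]:
    """Single-gene convenience wrapper.

    Returns (beta_trainer, beta_comparator, F, p_interaction) for one gene's
    annotated sample values.
    """
    frame = ExpressionMatrix(
        values=pd.DataFrame([values.to_numpy(dtype=float)],
                            index=["gene"], columns=values.index),
        annotations=annotations,
    )
    row = factorial_test_matrix(frame).iloc[0]
    return (
        float(row["beta_trainer"]),
        float(row["beta_comparator"]),
        float(row["F"]),
        float(row["p_interaction"]),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j>=i} p_(j) * m / j on the sorted vector, capped at 1 and
    mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        bad = p[np.isnan(p) | (p < 0) | (p > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_differential(
    matrix: ExpressionMatrix,
    clusters: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    per_cluster: bool = True,
) -> pd.DataFrame:
    """Factorial tests plus BH adjustment and responder selection.

    BH is applied within each K-means cluster by default (the clusters scope
    the test family), or globally with ``per_cluster=False``.  A gene is
    selected when its adjusted p is below alpha and its trainer response
    exceeds its comparator response.
    """
    stats_df = factorial_test_matrix(matrix)
    clusters = clusters.reindex(stats_df.index)
    if clusters.isna().any():
        missing = clusters.index[clusters.isna()][0]
        raise ValueError(f"gene {missing!r} has no cluster label")
    out = stats_df.copy()
    out.insert(0, "cluster", clusters.astype(int))
    if per_cluster:
        q = np.empty(len(out))
        for _, idx in out.groupby("cluster").groups.items():
            pos = out.index.get_indexer(idx)
            q[pos] = bh_adjust(out["p_interaction"].to_numpy()[pos])
        out["p_adjusted"] = q
    else:
        out["p_adjusted"] = bh_adjust(out["p_interaction"].to_numpy())
    out["selected"] = (out["p_adjusted"] < alpha) & (out["interaction_estimate"] > 0)
    out.index.name = "gene"
    return out


def select_responders(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    per_cluster: bool = True,
) -> list[str]:
    """Genes with BH-adjusted interaction p < alpha and a stronger trainer
    than comparator response.

    ``results`` must carry p_interaction, interaction_estimate and cluster
    columns; the BH family is re-derived here so alpha and scope can be
    varied without refitting.
    """
    p = results["p_interaction"].to_numpy()
    if per_cluster:
        q = np.empty(len(results))
        for _, idx in results.groupby("cluster").groups.items():
            pos = results.index.get_indexer(idx)
            q[pos] = bh_adjust(p[pos])
    else:
        q = bh_adjust(p)
    mask = (q < alpha) & (results["interaction_estimate"].to_numpy() > 0)
    return list(results.index[mask])
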