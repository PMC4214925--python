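"""Hypergeometric gene-set enrichment of the responder list.

For each gene set the universe-intersected membership is tested against the
responder list with the one-sided hypergeometric (Fisher exact) upper tail,
the standard construction for a molecular concept map over a discrete gene
list.  The enrichment score is -log10(p); the significance cutoff
score > 1.3 corresponds to p < 0.05.  BH-adjusted p-values over the merged
set family are reported alongside, and can optionally drive the cutoff.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

SCORE_THRESHOLD = 1.3  # -log10(p) > 1.3  <=>  p < 10**-1.3 ~ 0.05
MIN_SET_SIZE = 5
MAX_SET_SIZE = 500
_P_FLOOR = 1e-300  # keeps -log10 finite

RESULT_COLUMNS = (
    "set", "source", "N", "K", "n", "k", "p", "p_adjusted", "score", "significant",
)


def hypergeom_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: set size within the universe, n: list size,
    k: observed hits.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    responders,
    universe,
    collection: GeneSetCollection,
    score_threshold: float = SCORE_THRESHOLD,
    min_set_size: int = MIN_SET_SIZE,
    max_set_size: int = MAX_SET_SIZE,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every eligible set in the collection.

    Memberships are intersected with the universe before counting; sets whose
    intersected size falls outside [min_set_size, max_set_size] are excluded.
    P-values are BH-adjusted across all tested sets (the merged K/G/P/R
    family).  ``significant`` applies the -log10 cutoff to the raw p by
    default, to the adjusted p with ``use_adjusted``.
    """
    universe_set = set(universe)
    responder_set = set(responders)
    stray = responder_set - universe_set
    if stray:
        raise ValueError(f"responder {sorted(stray)[0]!r} is not in the universe")
    rows = []
    n_list = len(responder_set)
    n_universe = len(universe_set)
    for gs in collection:
        members = gs.members & universe_set
        size = len(members)
        if size < min_set_size or size > max_set_size:
            logger.info(
                "excluding %s: %d members in universe outside [%d, %d]",
                gs.qualified_name, size, min_set_size, max_set_size,
            )
            continue
        hits = len(members & responder_set)
        p = hypergeom_p(n_universe, size, n_list, hits)
        rows.append(
            dict(set=gs.qualified_name, source=gs.source, N=n_universe,
                 K=size, n=n_list, k=hits, p=p)
        )
    result = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS
                                         if c not in ("p_adjusted", "score",
                                                      "significant")])
    if result.empty:
        result["p_adjusted"] = pd.Series(dtype=float)
        result["score"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["p_adjusted"] = bh_adjust(result["p"].to_numpy())
    result["score"] = -np.log10(np.maximum(result["p"].to_numpy(), _P_FLOOR))
    gate = result["p_adjusted"] if use_adjusted else result["p"]
    result["significant"] = -np.log10(np.maximum(gate, _P_FLOOR)) > score_threshold
    return result.sort_values("set", kind="stable").reset_index(drop=True)
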