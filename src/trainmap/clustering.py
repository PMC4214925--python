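"""K-means clustering of per-gene response profiles.

Each gene is represented by the 4-vector (snr_trainer, snr_comparator,
response_trainer, response_comparator), standardized per dimension, so the
clusters capture both the magnitude and the reliability of the response to
each stimulus.  Clustering uses Lloyd's algorithm with k-means++ seeding and
keeps the best of several restarts by within-cluster sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

DEFAULT_K = 9
DEFAULT_SEED = 17
DEFAULT_RESTARTS = 10

PROFILE_COLUMNS = (
    "snr_trainer",
    "snr_comparator",
    "response_trainer",
    "response_comparator",
)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene id -> cluster label in {0..k-1}
    centroids: np.ndarray  # k x n_features, in standardized profile space
    k: int
    seed: int
    n_iter_run: int
    wcss: float

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def make_profiles(summary: pd.DataFrame) -> pd.DataFrame:
    """Standardize the response-summary columns to zero mean / unit sd.

    Constant dimensions are left at zero rather than divided by zero.
    """
    x = summary.loc[:, list(PROFILE_COLUMNS)].astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return (x - mu) / sd


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = DEFAULT_K,
    seed: int = DEFAULT_SEED,
    restarts: int = DEFAULT_RESTARTS,
) -> ClusterAssignment:
    """Partition gene profiles into k clusters, best of `restarts` runs.

    Deterministic for a given seed; fails if k exceeds the number of
    distinct profiles (no valid partition without empty clusters exists).
    """
    if k < 1:
        raise ValueError("k must be positive")
    if restarts < 1:
        raise ValueError("restarts must be positive")
    x = profiles.to_numpy(dtype=float)
    n_distinct = np.unique(x, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct profiles available"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(x)
    labels = pd.Series(km.labels_, index=profiles.index, name="cluster")
    counts = np.bincount(km.labels_, minlength=k)
    if (counts == 0).any():  # sklearn relocates empty clusters; guard anyway
        raise RuntimeError("k-means returned an empty cluster")
    return ClusterAssignment(
        labels=labels,
        centroids=km.cluster_centers_,
        k=k,
        seed=seed,
        n_iter_run=int(km.n_iter_),
        wcss=float(km.inertia_),
    )
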