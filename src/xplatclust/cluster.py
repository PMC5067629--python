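"""k-means coexpression clustering with a randomized-reference choice of k.

The combined fold-change profiles are clustered with Lloyd k-means (best of
``n_init`` random initializations).  The number of clusters is chosen by
comparing the average within-cluster variance of the real data against that
of a randomized reference built by independently permuting each column of the
profile matrix across genes — this destroys gene-level temporal structure
(the coexpression that k-means exploits) while preserving every column's
marginal distribution.  The chosen k is the smallest grid value at which the
real data's variance drops below the randomized reference's.

Centroids are subsequently reclustered with average-linkage (UPGMA)
hierarchical clustering for display ordering, and individual clusters can be
split into subclusters by cutting an average-linkage tree over their members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

__all__ = [
    "DEFAULT_K_GRID",
    "ClusterModel",
    "KSelectionTrace",
    "kmeans_cluster",
    "within_cluster_variance",
    "per_cluster_variance",
    "select_k",
    "recluster_centroids",
    "linkage_to_newick",
    "subcluster",
]

# Grid of candidate cluster counts: steps of five up to 50, then ten up to 100.
DEFAULT_K_GRID: tuple[int, ...] = tuple(range(5, 51, 5)) + tuple(range(60, 101, 10))


@dataclass
class ClusterModel:
    """A fitted k-means partition of the combined profiles.

    ``assignment`` maps gene id -> cluster id (1..k); ``centroids`` (k x D,
    indexed by cluster id) are exactly the means of their members' profiles.
    ``linkage``/``leaf_order`` hold the average-linkage dendrogram over
    centroids once :func:`recluster_centroids` has been applied.
    """

    k: int
    assignment: pd.Series
    centroids: pd.DataFrame
    within_cluster_variance: float
    seed: int
    n_init: int
    linkage: np.ndarray | None = None
    leaf_order: list[int] | None = None

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster_id])

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


@dataclass
class KSelectionTrace:
    """Per-k variances of the real and randomized data, and the chosen k."""

    k_grid: list[int]
    actual_variance: list[float]
    randomized_variance: list[float]
    chosen_k: int
    fell_through: bool = False
    skipped: list[int] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_grid,
                "actual_variance": self.actual_variance,
                "randomized_variance": self.randomized_variance,
            }
        )


def _as_matrix(profiles: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    X = profiles.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("profiles must be a gene x feature matrix with D >= 1")
    return X, profiles.index


def kmeans_cluster(
    profiles: pd.DataFrame, k: int, seed: int, n_init: int = 25
) -> ClusterModel:
    """Best-of-``n_init`` Lloyd k-means with Euclidean distance.

    Deterministic given ``seed``.  Centroids are recomputed as exact member
    means of the final assignment, and the reported within-cluster variance
    is the average over clusters of the mean squared member-to-centroid
    distance.
    """
    X, index = _as_matrix(profiles)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({X.shape[0]})")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_init,
        algorithm="lloyd",
        random_state=seed % (2**32),
    ).fit(X)
    labels = km.labels_ + 1  # cluster ids 1..k
    assignment = pd.Series(labels, index=index, name="cluster")
    centroids = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in range(1, k + 1)],
        index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=profiles.columns,
    )
    wcv = within_cluster_variance(profiles, assignment, centroids)
    return ClusterModel(
        k=k,
        assignment=assignment,
        centroids=centroids,
        within_cluster_variance=wcv,
        seed=seed,
        n_init=n_init,
    )


def per_cluster_variance(
    profiles: pd.DataFrame, assignment: pd.Series, centroids: pd.DataFrame
) -> pd.Series:
    """Mean squared Euclidean member-to-centroid distance, per cluster."""
    X, index = _as_matrix(profiles)
    labels = assignment.loc[index].to_numpy()
    out = {}
    for c in centroids.index:
        mask = labels == c
        if not mask.any():
            raise ValueError(f"cluster {c} has no members")
        d2 = ((X[mask] - centroids.loc[c].to_numpy()) ** 2).sum(axis=1)
        out[c] = float(d2.mean())
    return pd.Series(out, name="within_cluster_variance")


def within_cluster_variance(
    profiles: pd.DataFrame, assignment: pd.Series, centroids: pd.DataFrame
) -> float:
    """Average over clusters of the mean squared distance of members to their
    centroid; 0 iff every member coincides with its centroid."""
    return float(per_cluster_variance(profiles, assignment, centroids).mean())


def _randomize_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each column across genes (preserves marginals)."""
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = X[rng.permutation(X.shape[0]), j]
    return out


def select_k(
    profiles: pd.DataFrame,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    n_randomizations: int = 10,
    seed: int = 0,
    n_init: int = 10,
    margin: float = 0.1,
) -> KSelectionTrace:
    """Choose k by comparison against column-permuted randomized data.

    For each k in the grid, records the within-cluster variance of the real
    profiles and the mean over ``n_randomizations`` column-permuted datasets.
    ``chosen_k`` is the smallest grid k at which the actual variance drops
    below the randomized one by more than ``margin`` (relative): for data
    with no gene-level temporal structure the real and permuted matrices are
    exchangeable, so their variances differ only by k-means sampling
    fluctuation (a few percent); the margin keeps such coin-flip orderings
    from counting as a crossing.  If no k qualifies the trace falls through
    to max(k_grid) with ``fell_through`` set.  Grid values exceeding the
    gene count are skipped with a warning.
    """
    if not len(k_grid):
        raise ValueError("k_grid must be nonempty")
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    X, index = _as_matrix(profiles)
    rng = np.random.default_rng(seed)
    randomized = [
        pd.DataFrame(_randomize_columns(X, rng), index=index, columns=profiles.columns)
        for _ in range(n_randomizations)
    ]

    usable = [k for k in sorted(k_grid) if k <= X.shape[0]]
    skipped = [k for k in sorted(k_grid) if k > X.shape[0]]
    if skipped:
        warnings.warn(
            f"k values {skipped} exceed the gene count ({X.shape[0]}); skipped"
        )
    if not usable:
        raise ValueError("every k in the grid exceeds the number of genes")

    actual, rand_mean = [], []
    for k in usable:
        sub_seed = int(rng.integers(2**31))
        actual.append(
            kmeans_cluster(profiles, k, seed=sub_seed, n_init=n_init).within_cluster_variance
        )
        rand_vals = [
            kmeans_cluster(r, k, seed=sub_seed + j + 1, n_init=n_init).within_cluster_variance
            for j, r in enumerate(randomized)
        ]
        rand_mean.append(float(np.mean(rand_vals)))

    chosen, fell_through = None, False
    for k, a, r in zip(usable, actual, rand_mean):
        if a < (1.0 - margin) * r:
            chosen = k
            break
    if chosen is None:
        chosen = usable[-1]
        fell_through = True
        warnings.warn(
            "actual within-cluster variance never dropped below the randomized "
            f"reference; falling through to k={chosen}"
        )
    return KSelectionTrace(
        k_grid=usable,
        actual_variance=actual,
        randomized_variance=rand_mean,
        chosen_k=chosen,
        fell_through=fell_through,
        skipped=skipped,
    )


def recluster_centroids(centroids: pd.DataFrame) -> tuple[np.ndarray, list[int]]:
    """Average-linkage (UPGMA) hierarchical clustering of the centroids.

    Returns the scipy linkage matrix and the dendrogram leaf order expressed
    as cluster ids.  scipy's linkage is deterministic, breaking distance ties
    by the lower observation index (i.e. lower cluster id first).
    """
    ids = list(centroids.index)
    if len(ids) < 2:
        return np.empty((0, 4)), ids
    Z = hierarchy.linkage(centroids.to_numpy(dtype=float), method="average", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return Z, [ids[i] for i in order]


def linkage_to_newick(Z: np.ndarray, leaf_names: list) -> str:
    """Render a scipy linkage matrix as a Newick string (branch lengths are
    half the merge-height differences, UPGMA-style ultrametric)."""
    n = len(leaf_names)
    if n == 1:
        return f"{leaf_names[0]};"
    heights = {i: 0.0 for i in range(n)}
    # children are always built before parents in linkage row order
    parts: dict[int, str] = {}
    for i in range(n):
        parts[i] = str(leaf_names[i])
    for row in range(Z.shape[0]):
        i = n + row
        left, right = int(Z[row, 0]), int(Z[row, 1])
        height = Z[row, 2] / 2.0
        heights[i] = height
        parts[i] = (
            f"({parts[left]}:{height - heights[left]:.6g},"
            f"{parts[right]}:{height - heights[right]:.6g})"
        )
    return parts[2 * n - 2] + ";"


def subcluster(
    member_profiles: pd.DataFrame,
    n_subclusters: int | None = None,
    cut_height: float | None = None,
    parent_label: str | int | None = None,
) -> pd.Series:
    """Split one cluster's members by cutting an average-linkage tree.

    Exactly one of ``n_subclusters`` / ``cut_height`` must be given.  Labels
    are renumbered in order of first appearance; with ``parent_label`` they
    become nested strings ("15.1", "15.2", ...).
    """
    if (n_subclusters is None) == (cut_height is None):
        raise ValueError("give exactly one of n_subclusters or cut_height")
    X, index = _as_matrix(member_profiles)
    if X.shape[0] < 2:
        raise ValueError("subclustering needs >= 2 members")
    if n_subclusters is not None and not 1 <= n_subclusters <= X.shape[0]:
        raise ValueError("n_subclusters must be in [1, number of members]")
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    if n_subclusters is not None:
        raw = hierarchy.fcluster(Z, t=n_subclusters, criterion="maxclust")
    else:
        raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    # renumber in order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    if parent_label is not None:
        return pd.Series([f"{parent_label}.{l}" for l in labels], index=index, name="subcluster")
    return pd.Series(labels, index=index, name="subcluster")
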