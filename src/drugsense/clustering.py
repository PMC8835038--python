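"""Hierarchical clustering of a precomputed distance matrix with silhouette model selection.

The number of clusters k is chosen by maximizing the mean silhouette score

    s_i = (b_i - a_i) / max(a_i, b_i)

where a_i is the average distance of item i to its own cluster and b_i the
minimum average distance to any other cluster.  Items in singleton clusters
get s_i = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .transport import DistanceMatrix

__all__ = ["ClusteringResult", "hierarchical_clusters", "silhouette", "select_k"]

_LINKAGES = {"average", "single", "complete"}


@dataclass(frozen=True)
class ClusteringResult:
    ids: tuple
    labels: np.ndarray  # integer labels 1..k
    k: int
    silhouette_values: np.ndarray
    mean_silhouette: float

    def members(self, label: int) -> list:
        return [i for i, l in zip(self.ids, self.labels) if l == label]


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (permutation-stable output)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, l in enumerate(raw):
        if l not in mapping:
            mapping[l] = len(mapping) + 1
        out[i] = mapping[l]
    return out


def hierarchical_clusters(D: DistanceMatrix, k: int, method: str = "average") -> np.ndarray:
    """Cut the agglomerative merge tree of ``D`` at ``k`` clusters.

    Deterministic given D: scipy's linkage breaks merge ties by cluster index.
    """
    if method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    n = D.n
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    if k == n:
        return np.arange(1, n + 1)
    Z = linkage(squareform(D.values, checks=False), method=method)
    # Apply the first n-k merges of the tree: always yields exactly k clusters,
    # even when merge heights tie (fcluster's maxclust criterion does not).
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for merge_idx in range(n - k):
        a, b = int(Z[merge_idx, 0]), int(Z[merge_idx, 1])
        new = n + merge_idx
        parent[find(a)] = new
        parent[find(b)] = new
    roots = np.array([find(i) for i in range(n)])
    return _canonical_labels(roots)


def silhouette(D: DistanceMatrix, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-item silhouette values and their mean for a labeling of ``D``."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    d = D.values
    n = D.n
    s = np.zeros(n)
    members = {l: np.flatnonzero(labels == l) for l in uniq}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            s[i] = 0.0  # singleton convention
            continue
        a = d[i, own[own != i]].mean()
        b = min(d[i, members[l]].mean() for l in uniq if l != labels[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s, float(s.mean())


def select_k(
    D: DistanceMatrix, k_min: int = 2, k_max: int = 15, method: str = "average"
) -> ClusteringResult:
    """Best clustering over k in [k_min, k_max] by mean silhouette; ties favor smaller k."""
    n = D.n
    if k_max > n - 1:
        k_max = n - 1
    if k_min > k_max:
        raise ValueError("k_min exceeds k_max (too few items)")
    best: ClusteringResult | None = None
    for k in range(k_min, k_max + 1):
        labels = hierarchical_clusters(D, k, method=method)
        s, mean_s = silhouette(D, labels)
        if best is None or mean_s > best.mean_silhouette + 1e-12:
            best = ClusteringResult(D.ids, labels, k, s, mean_s)
    assert best is not None
    return best
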