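"""K-means partitioning of gene-anchored occupancy patterns.

The number of clusters is fixed a priori per analysis (2 for expressed vs
silent or histone splits, 4 for the narrow/broad pause taxonomy).  Distances
are Euclidean on the density rows; no row scaling is applied by default
because absolute occupancy carries signal (highly expressed broad-pause
genes separate from weakly expressed ones partly by level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .coverage import AnchorMatrix

__all__ = ["ClusterResult", "kmeans_cluster", "cluster_profiles", "adjusted_rand_index", "heatmap_order"]


@dataclass
class ClusterResult:
    k: int
    assignments: dict[str, int]
    centroids: np.ndarray
    seed: int
    restarts: int
    inertia: float

    def labels_for(self, genes) -> np.ndarray:
        return np.array([self.assignments[g] for g in genes])

    def sizes(self) -> dict[int, int]:
        out = {j: 0 for j in range(self.k)}
        for c in self.assignments.values():
            out[c] += 1
        return out

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tcluster\n")
            for g, c in self.assignments.items():
                fh.write(f"{g}\t{c}\n")


def kmeans_cluster(
    m: AnchorMatrix,
    k: int,
    seed: int = 0,
    restarts: int = 50,
    row_scaling: str = "none",
) -> ClusterResult:
    """Best-of-restarts Lloyd's K-means with k-means++ seeding.

    Deterministic for a fixed seed.  ``row_scaling`` optionally rescales each
    row to unit maximum or to z-scores before clustering.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m.n_genes:
        raise ValueError(f"k={k} exceeds {m.n_genes} rows")
    X = np.asarray(m.values, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    if row_scaling == "unit_max":
        mx = X.max(axis=1, keepdims=True)
        X = np.where(mx > 0, X / np.where(mx > 0, mx, 1), X)
    elif row_scaling == "zscore":
        sd = X.std(axis=1, keepdims=True)
        X = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1)
    elif row_scaling != "none":
        raise ValueError(f"unknown row_scaling {row_scaling!r}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    labels = km.labels_.astype(int)
    # recompute centroids as exact row means of the (unscaled-space) clusters
    centroids = np.vstack(
        [X[labels == j].mean(axis=0) if (labels == j).any() else km.cluster_centers_[j] for j in range(k)]
    )
    assignments = dict(zip(m.genes, labels.tolist()))
    return ClusterResult(k, assignments, centroids, seed, restarts, float(km.inertia_))


def cluster_profiles(m: AnchorMatrix, cr: ClusterResult):
    """Per-cluster mean density vectors and member counts.

    Returns (profiles: k x bins array, sizes: dict cluster -> n).
    """
    labels = cr.labels_for(m.genes)
    profiles = np.zeros((cr.k, m.n_bins))
    sizes = {}
    for j in range(cr.k):
        mask = labels == j
        sizes[j] = int(mask.sum())
        if sizes[j]:
            profiles[j] = m.values[mask].mean(axis=0)
    assert sum(sizes.values()) == m.n_genes
    return profiles, sizes


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected partition agreement in [-1, 1]."""
    a = list(a)
    b = list(b)
    if len(a) != len(b):
        raise ValueError(f"label lengths differ: {len(a)} vs {len(b)}")
    return float(adjusted_rand_score(a, b))


def heatmap_order(m: AnchorMatrix, cr: ClusterResult) -> list[int]:
    """Row permutation for heatmap display: cluster-major, then descending
    row sum within each cluster."""
    labels = cr.labels_for(m.genes)
    sums = m.values.sum(axis=1)
    return sorted(range(m.n_genes), key=lambda i: (labels[i], -sums[i], m.genes[i]))
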