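"""Whole-transcriptome structure: PCA over time points, sample distances,
and hierarchical clustering of genes.

PCA is the Q-mode convention: singular value decomposition of the matrix
with time points in rows and genes in columns, each gene column mean
centered (no variance scaling). Scores place the time points in component
space; loadings are the gene directions. Distances between time points are
plain Euclidean over genes. Gene clustering is agglomerative with average
linkage (UPGMA) on 1 - uncentered correlation, the cosine-type similarity
s = sum(x*y) / sqrt(sum(x^2) * sum(y^2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PcaResult",
    "Dendrogram",
    "pca_timepoints",
    "euclidean_distance_matrix",
    "uncentered_correlation",
    "uncentered_correlation_distances",
    "average_linkage_cluster",
]


@dataclass
class PcaResult:
    scores: np.ndarray  # time points x components
    loadings: np.ndarray  # genes x components, orthonormal columns
    variance_fraction: np.ndarray  # per component, sums to 1


@dataclass
class Dendrogram:
    """UPGMA merge tree over gene leaves (scipy linkage encoding).

    ``merges`` row k merges clusters with ids Z[k,0], Z[k,1] at height
    Z[k,2] into new cluster n+k; average linkage makes heights
    nondecreasing along the merge sequence.
    """

    leaf_ids: list[str]
    merges: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        n = len(self.leaf_ids)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaf_ids[i] for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.merges):
            i, j = int(i), int(j)
            bi = h - height[i]
            bj = h - height[j]
            node[n + k] = f"({node[i]}:{bi:.10g},{node[j]}:{bj:.10g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";"


def pca_timepoints(log2_matrix: np.ndarray) -> PcaResult:
    """PCA of a time points x genes matrix of log2 data via SVD.

    Each gene column is centered across time points; no scaling. Component
    signs are arbitrary.
    """
    X = np.asarray(log2_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 time points and >= 2 genes")
    centered = X - X.mean(axis=0, keepdims=True)
    total_var = (centered**2).sum()
    if total_var == 0:
        raise ValueError("constant matrix: variance fractions undefined")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    return PcaResult(
        scores=U * s,
        loadings=Vt.T,
        variance_fraction=s**2 / (s**2).sum(),
    )


def euclidean_distance_matrix(log2_matrix: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distances between rows (time points) over genes."""
    X = np.asarray(log2_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    return squareform(pdist(X, metric="euclidean"))


def uncentered_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine-type similarity sum(xy)/sqrt(sum(x^2)sum(y^2)) in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = float(x @ x)
    ny = float(y @ y)
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float(np.clip((x @ y) / np.sqrt(nx * ny), -1.0, 1.0))


def uncentered_correlation_distances(vectors: np.ndarray) -> np.ndarray:
    """Condensed 1 - uncentered-correlation distances between rows."""
    V = np.asarray(vectors, dtype=float)
    norms = np.sqrt((V**2).sum(axis=1))
    if np.any(norms == 0):
        raise ValueError("zero vector among cluster inputs")
    sim = (V @ V.T) / np.outer(norms, norms)
    np.clip(sim, -1.0, 1.0, out=sim)
    return squareform(1.0 - sim, checks=False)


def average_linkage_cluster(
    vectors: np.ndarray, leaf_ids: Sequence[str] | None = None
) -> Dendrogram:
    """UPGMA on 1 - uncentered correlation between gene profiles.

    Inter-cluster distance is the arithmetic mean of all cross-pair
    distances; the closest pair merges first.
    """
    V = np.asarray(vectors, dtype=float)
    if V.shape[0] < 2:
        raise ValueError("need >= 2 genes to cluster")
    ids = list(leaf_ids) if leaf_ids is not None else [str(i) for i in range(V.shape[0])]
    if len(ids) != V.shape[0]:
        raise ValueError("one leaf id per row required")
    Z = linkage(uncentered_correlation_distances(V), method="average")
    return Dendrogram(ids, Z)
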