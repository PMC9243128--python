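"""Correlation signatures and Ward hierarchical clustering.

The feature-clustering convention follows case/control glycomics practice:
compute the Spearman correlation matrix of the expression signatures,
convert to a dissimilarity ``d = 1 - r``, and cluster agglomeratively with
the Ward criterion.  The clustered image map (CIM) applies independent row
and column clusterings and reorders the matrix by both leaf orders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from glycoblock.errors import ComputationError, ValidationError

__all__ = [
    "Dendrogram",
    "correlation_matrix",
    "ward_cluster",
    "corr_distance",
    "clustered_image_map",
]


@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    ``linkage`` is the standard (n-1) x 4 merge table: each row merges two
    node ids (original leaves are 0..n-1, internal nodes continue upward)
    at a given height with the merged cluster size.  Under the Ward
    criterion the heights are non-decreasing.
    """

    linkage: np.ndarray
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merges(self) -> np.ndarray:
        return self.linkage[:, :2].astype(int)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> tuple[int, ...]:
        return tuple(hierarchy.leaves_list(self.linkage))

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (1..k) from cutting the tree into k groups."""
        if k > self.n_leaves:
            raise ValidationError(f"cannot cut {self.n_leaves} leaves into {k} clusters")
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Nested-parenthesis text rendering with merge heights."""
        n = self.n_leaves
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for row_i, (a, b) in enumerate(self.merges):
            h = self.heights[row_i]
            nodes[n + row_i] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.6g}"
        return nodes[n + len(self.merges) - 1] + ";"


def correlation_matrix(X: np.ndarray, method: str = "spearman",
                       names: Sequence[str] | None = None) -> np.ndarray:
    """Column-wise correlation matrix; symmetric with unit diagonal."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValidationError("correlation needs at least 3 samples")
    const = np.where(X.std(axis=0) == 0)[0]
    if const.size:
        which = [names[j] if names else str(j) for j in const]
        raise ComputationError(f"constant columns have undefined correlation: {which}")
    if method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        r = np.corrcoef(ranks, rowvar=False)
    elif method == "pearson":
        r = np.corrcoef(X, rowvar=False)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def corr_distance(r: np.ndarray) -> np.ndarray:
    """Dissimilarity ``1 - r`` from a correlation matrix, zero diagonal."""
    d = 1.0 - np.asarray(r, dtype=float)
    np.fill_diagonal(d, 0.0)
    return d


def ward_cluster(data: np.ndarray, k: int, labels: Sequence[str] | None = None,
                 precomputed: bool = False) -> tuple[Dendrogram, np.ndarray]:
    """Ward agglomerative clustering with a k-group cut.

    ``data`` is either an items x features profile matrix (Euclidean
    distances computed internally) or, with ``precomputed``, a square
    dissimilarity matrix.  Returns the dendrogram and integer labels 1..k.
    """
    data = np.asarray(data, dtype=float)
    if precomputed:
        if data.shape[0] != data.shape[1]:
            raise ValidationError("precomputed distance matrix must be square")
        n = data.shape[0]
        condensed = squareform(data, checks=False)
    else:
        n = data.shape[0]
        condensed = pdist(data, metric="euclidean")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of items {n}")
    if labels is None:
        labels = tuple(str(i) for i in range(n))
    linkage = hierarchy.linkage(condensed, method="ward")
    dend = Dendrogram(linkage=linkage, labels=tuple(labels))
    return dend, dend.cut(k)


def clustered_image_map(matrix: np.ndarray,
                        row_labels: Sequence[str] | None = None,
                        col_labels: Sequence[str] | None = None,
                        ) -> tuple[Dendrogram, Dendrogram, np.ndarray]:
    """Independent Ward clusterings of rows and columns, with the matrix
    reordered by both leaf orders."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValidationError("clustered image map needs a matrix of at least 2 x 2")
    row_d, _ = ward_cluster(matrix, k=1, labels=row_labels)
    col_d, _ = ward_cluster(matrix.T, k=1, labels=col_labels)
    ordered = matrix[np.asarray(row_d.leaf_order)][:, np.asarray(col_d.leaf_order)]
    return row_d, col_d, ordered
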