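"""Correlation-based agglomerative clustering — the linear baseline.

Pearson correlation only captures linear association, so hierarchical
clustering on a correlation-derived dissimilarity misplaces variables that
are purely nonlinear transforms of their cluster's generator (e.g. v^2 of a
symmetric variable is uncorrelated with v).  This module provides that
baseline: the correlation matrix, the d = 1 - |rho| (or 1 - rho) map, and
group-average (UPGMA) agglomerative clustering cut at K clusters.

The absolute-value map treats strong negative linear dependence as
similarity, so only genuinely nonlinear dependence defeats the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from ._utils import InputError, as_variable_matrix, check_square_symmetric
from .dpmm import Partition

__all__ = ["pearson_matrix", "correlation_dissimilarity", "Dendrogram",
           "hc_cluster"]


def pearson_matrix(data) -> pd.DataFrame:
    """Pairwise Pearson correlations of the columns; unit diagonal."""
    X, names = as_variable_matrix(data)
    if np.any(X.std(axis=0) == 0):
        j = int(np.flatnonzero(X.std(axis=0) == 0)[0])
        raise InputError(f"variable {names[j]!r} is constant; correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(np.clip(R, -1.0, 1.0), index=names, columns=names)


def correlation_dissimilarity(rho, kind: str = "abs") -> pd.DataFrame:
    """Map correlations to dissimilarities: 1 - |rho| (default) or 1 - rho."""
    names = list(rho.index) if isinstance(rho, pd.DataFrame) else None
    R = check_square_symmetric(rho, "correlation matrix")
    if kind == "abs":
        D = 1.0 - np.abs(R)
    elif kind == "signed":
        D = 1.0 - R
    else:
        raise InputError("kind must be 'abs' or 'signed'")
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    if names is None:
        names = [f"v{i + 1}" for i in range(D.shape[0])]
    return pd.DataFrame(D, index=names, columns=names)


@dataclass
class Dendrogram:
    """Agglomerative merge history: (cluster_a, cluster_b, height) per step.

    Ids 0..N-1 are leaves; id N+i is the cluster created at merge step i.
    Group-average linkage guarantees nondecreasing heights.
    """

    merges: list
    leaves: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["cluster_a", "cluster_b", "height"])

    def to_newick(self) -> str:
        """Newick string with branch lengths (half the merge-height gaps)."""
        n = len(self.leaves)
        Z = np.array([[a, b, h, 0] for a, b, h in self.merges], dtype=float)
        # fill subtree sizes required by scipy's linkage format
        sizes = {i: 1 for i in range(n)}
        for i, (a, b, _h) in enumerate(self.merges):
            sizes[n + i] = sizes[int(a)] + sizes[int(b)]
            Z[i, 3] = sizes[n + i]
        root = to_tree(Z)

        def rec(node, parent_height):
            bl = max(parent_height - node.dist, 0.0) / 2.0
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{bl:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{bl:.6g}"

        return rec(root, root.dist) + ";"


def hc_cluster(delta, n_clusters: int):
    """Group-average (UPGMA) agglomerative clustering cut at ``n_clusters``.

    At each step the two clusters with the smallest average cross-pair
    dissimilarity are merged.  Returns ``(Partition, Dendrogram)``; labels
    are normalized to order of first appearance.
    """
    names = list(delta.index) if isinstance(delta, pd.DataFrame) else None
    D = check_square_symmetric(delta, "dissimilarity matrix")
    n = D.shape[0]
    if names is None:
        names = [f"v{i + 1}" for i in range(n)]
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise InputError("dissimilarity matrix must have a zero diagonal")
    if not 1 <= n_clusters <= n:
        raise InputError(f"n_clusters must be in [1, {n}]")
    Dz = D.copy()
    np.fill_diagonal(Dz, 0.0)
    Z = linkage(squareform(Dz, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    part = Partition.from_labels(labels)
    merges = [(int(a), int(b), float(h)) for a, b, h, _cnt in Z]
    return part, Dendrogram(merges=merges, leaves=list(names))
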