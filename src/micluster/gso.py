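"""Per-cluster Gram-Schmidt orthonormalization of the design matrix.

Variables inside a cluster are mutually redundant by construction; fitting a
regression on them directly is ill-conditioned.  Each cluster's columns are
therefore turned into an orthonormal set spanning the same space: the first
column is normalized, every subsequent column has its projections on the
previous orthonormal vectors removed and is then normalized.  Columns that
are (numerically) linear combinations of their predecessors are dropped and
reported, so each block has full column rank.

Processing order is the original column order by default (deterministic,
transparent); ``order='variance'`` processes columns by decreasing sample
variance instead.  Columns are mean-centered before orthonormalization by
default — the regression intercept absorbs the means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import InputError, as_variable_matrix
from .dpmm import Partition

__all__ = ["gram_schmidt_block", "OrthonormalBlock", "OrthonormalBlocks",
           "orthonormalize_clusters", "ClusterOrthonormalizer"]

DEFAULT_TOL = 1e-8


def gram_schmidt_block(V, tol: float = DEFAULT_TOL):
    """Classical Gram-Schmidt on the columns of ``V`` (in the given order).

    Returns ``(W, kept, dropped)`` where ``W`` has orthonormal columns
    (re-orthogonalized once for numerical accuracy), ``kept`` lists the
    retained input column indices and ``dropped`` those whose residual after
    projection fell below ``tol`` times their original norm.

    Raises on an exactly zero input column.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] < 1 or V.shape[0] < 1:
        raise InputError("V must be a non-empty 2-D matrix")
    if tol <= 0:
        raise InputError("tol must be positive")
    basis: list[np.ndarray] = []
    kept: list[int] = []
    dropped: list[int] = []
    for j in range(V.shape[1]):
        v = V[:, j]
        nv = np.linalg.norm(v)
        if nv == 0:
            raise InputError(f"column {j} is identically zero")
        r = v.copy()
        for _ in range(2):  # second pass controls cancellation error
            for w in basis:
                r -= (w @ r) * w
        rn = np.linalg.norm(r)
        if rn < tol * nv:
            dropped.append(j)
            continue
        basis.append(r / rn)
        kept.append(j)
    W = np.column_stack(basis)
    return W, kept, dropped


@dataclass
class OrthonormalBlock:
    """One cluster's orthonormal design block."""

    cluster: int
    members: list                # variable names in processing order
    kept: list                   # names actually retained
    dropped: list                # names dropped as linear combinations
    W: np.ndarray                # N_s x p_k, W'W = I
    transform: np.ndarray        # p_k x p_k map: centered kept columns @ transform = W
    means: np.ndarray            # training means of the kept columns (0 if uncentered)
    column_names: list = field(default_factory=list)  # synthesized c{k}_w{m}


@dataclass
class OrthonormalBlocks:
    """Concatenated per-cluster orthonormal blocks with group structure."""

    blocks: list
    names: list                  # original variable names

    @property
    def W(self) -> np.ndarray:
        return np.concatenate([b.W for b in self.blocks], axis=1)

    @property
    def group_index(self) -> np.ndarray:
        """Cluster id of every column of ``W``."""
        return np.concatenate(
            [np.full(b.W.shape[1], b.cluster, dtype=int) for b in self.blocks])

    @property
    def column_names(self) -> list:
        return [c for b in self.blocks for c in b.column_names]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, columns=self.column_names)

    def transform(self, data) -> np.ndarray:
        """Apply the fitted orthonormalizing map to new samples."""
        X, names = as_variable_matrix(data, min_samples=1, min_variables=1)
        if names != self.names:
            lookup = {nm: i for i, nm in enumerate(names)}
            missing = [nm for nm in self.names if nm not in lookup]
            if missing:
                raise InputError(f"new data lacks variables {missing}")
            X = X[:, [lookup[nm] for nm in self.names]]
            names = list(self.names)
        cols = []
        name_pos = {nm: i for i, nm in enumerate(self.names)}
        for b in self.blocks:
            idx = [name_pos[nm] for nm in b.kept]
            cols.append((X[:, idx] - b.means) @ b.transform)
        return np.concatenate(cols, axis=1)


def orthonormalize_clusters(data, partition, tol: float = DEFAULT_TOL,
                            center: bool = True,
                            order: str = "input") -> OrthonormalBlocks:
    """Orthonormalize each cluster's variables independently.

    Parameters
    ----------
    data : DataFrame or array, samples x variables
    partition : Partition or label vector over the columns of ``data``
    center : bool
        Mean-center columns first (the intercept handles means downstream).
    order : {'input', 'variance'}
        Column processing order inside each cluster.
    """
    X, names = as_variable_matrix(data, min_variables=1)
    if not isinstance(partition, Partition):
        partition = Partition.from_labels(partition)
    labels = partition.labels
    if labels.size != X.shape[1]:
        raise InputError("partition length must equal the number of variables")
    if order not in ("input", "variance"):
        raise InputError("order must be 'input' or 'variance'")

    blocks = []
    for k in range(partition.n_clusters):
        idx = np.flatnonzero(labels == k)
        if order == "variance":
            idx = idx[np.argsort(-X[:, idx].var(axis=0), kind="stable")]
        Vk = X[:, idx]
        if center:
            means = Vk.mean(axis=0)
            Vk = Vk - means
        else:
            means = np.zeros(idx.size)
        try:
            W, kept, dropped = gram_schmidt_block(Vk, tol=tol)
        except InputError as exc:
            raise InputError(f"cluster {k}: {exc}") from exc
        # Upper-triangular map T with (centered kept columns) @ T = W;
        # R = W'V restricted to kept columns is the GSO triangular factor.
        R = W.T @ Vk[:, kept]
        T = np.linalg.solve(R, np.eye(R.shape[0]))
        blocks.append(OrthonormalBlock(
            cluster=k,
            members=[names[i] for i in idx],
            kept=[names[idx[i]] for i in kept],
            dropped=[names[idx[i]] for i in dropped],
            W=W,
            transform=T,
            means=means[kept],
            column_names=[f"c{k}_w{m + 1}" for m in range(W.shape[1])],
        ))
    return OrthonormalBlocks(blocks=blocks, names=names)


class ClusterOrthonormalizer(BaseEstimator, TransformerMixin):
    """Transformer applying per-cluster Gram-Schmidt orthonormalization.

    The partition over variables is passed at fit time::

        orth = ClusterOrthonormalizer().fit(X, labels)
        W_train = orth.transform(X)
        W_test = orth.transform(X_test)

    Attributes
    ----------
    blocks_ : OrthonormalBlocks
    group_index_ : ndarray mapping design columns to cluster ids
    """

    def __init__(self, tol: float = DEFAULT_TOL, center: bool = True,
                 order: str = "input"):
        self.tol = tol
        self.center = center
        self.order = order

    def fit(self, X, y=None):
        if y is None:
            raise InputError("pass the variable partition as the second argument")
        self.blocks_ = orthonormalize_clusters(
            X, y, tol=self.tol, center=self.center, order=self.order)
        self.group_index_ = self.blocks_.group_index
        self.column_names_ = self.blocks_.column_names
        return self

    def transform(self, X):
        return self.blocks_.transform(X)

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y)
        return self.blocks_.W
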