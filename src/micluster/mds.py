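"""Classical (metric) multidimensional scaling of a dissimilarity matrix.

The embedding reconstructs the Gram matrix B = -1/2 * H D^(2) H, where H is
the centering matrix I - (1/N) 11' and D^(2) the elementwise-squared
dissimilarities, then eigendecomposes B = V L V' and takes Y = V_d L_d^(1/2)
over the top positive eigenpairs.  For Euclidean input this recovers the
configuration exactly; reciprocal-MI dissimilarities are generally
non-Euclidean, so B can have negative eigenvalues, which are discarded and
reported as a diagnostic mass fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import InputError, NumericalError, check_square_symmetric

__all__ = ["EmbeddingCoordinates", "double_center", "embed", "classical_mds",
           "choose_dim", "ClassicalMDS"]


@dataclass
class EmbeddingCoordinates:
    """Low-dimensional feature vectors for N variables.

    ``Y[i]`` is variable i's coordinate vector; ``eigenvalues`` are the
    retained (strictly positive, decreasing) eigenvalues of the Gram matrix.
    """

    Y: np.ndarray
    eigenvalues: np.ndarray
    names: list = field(default_factory=list)
    negative_eigenvalue_mass: float = 0.0

    @property
    def n_components(self) -> int:
        return self.Y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"y{j + 1}" for j in range(self.Y.shape[1])]
        idx = self.names if self.names else range(self.Y.shape[0])
        return pd.DataFrame(self.Y, index=idx, columns=cols)


def double_center(delta) -> np.ndarray:
    """Gram matrix B = -1/2 H D^(2) H from a zero-diagonal dissimilarity matrix.

    Rows and columns of the result sum to zero.
    """
    D = check_square_symmetric(delta, "dissimilarity matrix")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise InputError("dissimilarity matrix must have a zero diagonal")
    D2 = D ** 2
    row = D2.mean(axis=1, keepdims=True)
    col = D2.mean(axis=0, keepdims=True)
    grand = D2.mean()
    B = -0.5 * (D2 - row - col + grand)
    return (B + B.T) / 2.0


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude component positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def choose_dim(positive_eigenvalues: np.ndarray, frac: float = 0.9) -> int:
    """Smallest d whose top-d eigenvalues carry >= ``frac`` of the positive mass."""
    w = np.asarray(positive_eigenvalues, dtype=float)
    if w.size == 0:
        raise NumericalError("no positive eigenvalue to choose a dimension from")
    cum = np.cumsum(w) / w.sum()
    return int(np.searchsorted(cum, frac) + 1)


def embed(B, d: int, names=None) -> EmbeddingCoordinates:
    """Spectral embedding of a Gram matrix into at most ``d`` dimensions.

    Only positive eigenpairs are retained; if fewer than ``d`` exist the
    returned dimension is reduced (with a warning).  Eigenvector signs are
    fixed deterministically for backend-independent output.
    """
    if d < 1:
        raise InputError(f"d must be >= 1, got {d}")
    Bm = check_square_symmetric(B, "Gram matrix")
    w, V = np.linalg.eigh(Bm)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(abs(w[0]), abs(w[-1]), 1.0) * 1e-12
    pos = w > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise NumericalError("Gram matrix has no positive eigenvalue")
    k = min(d, n_pos)
    if k < d:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; embedding in {k} dimensions "
            f"instead of {d}", RuntimeWarning)
    total = np.abs(w).sum()
    neg_mass = float(np.abs(w[w < -tol]).sum() / total) if total > 0 else 0.0
    Vk = _fix_signs(V[:, :k])
    Y = Vk * np.sqrt(w[:k])
    names = list(names) if names is not None else []
    return EmbeddingCoordinates(Y=Y, eigenvalues=w[:k].copy(), names=names,
                                negative_eigenvalue_mass=neg_mass)


def classical_mds(delta, n_components: int = 2, dim_auto: bool = False,
                  names=None) -> EmbeddingCoordinates:
    """Dissimilarities -> double-centered Gram matrix -> spectral embedding."""
    if names is None and isinstance(delta, pd.DataFrame):
        names = [str(c) for c in delta.index]
    B = double_center(delta)
    if dim_auto:
        w = np.linalg.eigvalsh(B)[::-1]
        tol = max(abs(w[0]), abs(w[-1]), 1.0) * 1e-12
        n_components = choose_dim(w[w > tol])
    return embed(B, n_components, names=names)


class ClassicalMDS(BaseEstimator):
    """Classical-scaling embedding estimator over a precomputed dissimilarity.

    Parameters
    ----------
    n_components : int, default 2
        Target embedding dimension (reduced if fewer positive eigenvalues).
    dim_auto : bool, default False
        Pick the smallest dimension explaining >= 90% of the positive
        eigenvalue mass, overriding ``n_components``.

    Attributes
    ----------
    embedding_ : ndarray (N, d)
    eigenvalues_ : ndarray (d,)
    negative_eigenvalue_mass_ : float
    names_ : list of str
    """

    def __init__(self, n_components: int = 2, dim_auto: bool = False):
        self.n_components = n_components
        self.dim_auto = dim_auto

    def fit(self, X, y=None):
        coords = classical_mds(X, self.n_components, self.dim_auto)
        self.coordinates_ = coords
        self.embedding_ = coords.Y
        self.eigenvalues_ = coords.eigenvalues
        self.negative_eigenvalue_mass_ = coords.negative_eigenvalue_mass
        self.names_ = coords.names
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_
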