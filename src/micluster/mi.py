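"""Histogram mutual information and reciprocal-MI dissimilarities.

Variables (columns of a samples x variables matrix) are compared with the
plug-in histogram estimator of mutual information

    MI(x, y) = sum_{k,l} p(k, l) * log[ p(k, l) / (p(k) p(l)) ]

on a B x B equal-width grid over each variable's observed range, with the
convention 0*log 0 = 0.  MI quantifies linear *and* nonlinear interdependence,
which is what makes it a better variable-to-variable similarity than the
Pearson correlation when variables are nonlinear transforms of one another.

The reciprocal delta_ij = 1 / MI(v_i, v_j) serves as a dissimilarity for the
downstream embedding and clustering; near-independent pairs (MI ~ 0) are
capped at ``delta_max`` so the dissimilarity matrix stays finite, and the
diagonal is forced to zero to respect the metric-scaling convention that
self-dissimilarity vanishes.

Notes on the estimator
----------------------
* Bin edges are equal-width over [min, max]; interior edges are right-closed
  (a value exactly on an edge falls in the lower bin).
* The plug-in estimate is positively biased for independent variables; the
  bias shrinks as the sample size grows at fixed bin count.
* The default bin count is B = floor(sqrt(N_s / 5)), clamped to [2, 50]
  (B = 14 at N_s = 1000); any rule of the sample size can be substituted via
  ``n_bins``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import InputError, as_variable_matrix, check_square_symmetric

__all__ = [
    "HistogramSpec",
    "default_n_bins",
    "independence_mi_floor",
    "auto_delta_max",
    "estimate_mi",
    "column_entropy",
    "mi_matrix",
    "dissimilarity_from_mi",
    "MutualInformationDissimilarity",
]

DEFAULT_DELTA_MAX = 1e3
_LN2 = math.log(2.0)


def default_n_bins(n_samples: int) -> int:
    """Bin count from sample size: floor(sqrt(N_s/5)), clamped to [2, 50]."""
    if n_samples < 2:
        raise InputError("need at least 2 samples to bin")
    return int(np.clip(int(math.sqrt(n_samples / 5.0)), 2, 50))


def independence_mi_floor(n_samples: int, n_bins: int) -> float:
    """Expected plug-in MI of independent variables: (B-1)^2 / (2 N_s) nats.

    This is the first-order (Miller-Madow) small-sample bias of the B x B
    histogram estimator; MI values at or below it carry no dependence signal.
    """
    return (n_bins - 1) ** 2 / (2.0 * n_samples)


def auto_delta_max(n_samples: int, n_bins: int,
                   hard_cap: float = DEFAULT_DELTA_MAX) -> float:
    """Default dissimilarity cap: the reciprocal of the independence bias.

    Beyond 1/bias a reciprocal-MI distance reflects estimator noise, not
    weaker dependence; capping there makes all (near-)independent pairs
    equally and maximally distant instead of scattering them over noisy
    large distances that dominate the squared-dissimilarity embedding.
    """
    return float(min(hard_cap, 1.0 / independence_mi_floor(n_samples, n_bins)))


@dataclass(frozen=True)
class HistogramSpec:
    """Binning rule for the 2-D histogram MI estimator.

    ``n_bins=None`` means derive B from the sample size (``from_sample_size``
    strategy); an explicit positive integer fixes B.
    """

    n_bins: int | None = None
    base: str = "nats"  # or "bits"
    on_constant: str = "error"  # or "zero"

    def __post_init__(self):
        if self.n_bins is not None and self.n_bins < 2:
            raise InputError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.base not in ("nats", "bits"):
            raise InputError(f"base must be 'nats' or 'bits', got {self.base!r}")
        if self.on_constant not in ("error", "zero"):
            raise InputError("on_constant must be 'error' or 'zero'")

    def resolve_bins(self, n_samples: int) -> int:
        return self.n_bins if self.n_bins is not None else default_n_bins(n_samples)


def _bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray | None:
    """Equal-width bin index per sample; None for a constant vector.

    Interior edges are right-closed so ties at an edge go to the lower bin.
    """
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return None
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.digitize(x, edges[1:-1], right=True)


def _mi_from_indices(ix: np.ndarray, iy: np.ndarray, n_bins: int) -> float:
    """Plug-in MI (nats) from pre-binned index vectors."""
    n = ix.size
    counts = np.bincount(ix * n_bins + iy, minlength=n_bins * n_bins)
    counts = counts.reshape(n_bins, n_bins)
    p = counts / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mask = p > 0
    mi = float(np.sum(p[mask] * (np.log(p[mask]) - np.log(np.outer(px, py)[mask]))))
    return max(mi, 0.0)


def _convert(mi_nats: float, base: str) -> float:
    return mi_nats / _LN2 if base == "bits" else mi_nats


def estimate_mi(x, y, spec: HistogramSpec | None = None, *,
                n_bins: int | None = None, base: str | None = None,
                on_constant: str | None = None) -> float:
    """Plug-in histogram mutual information between two sample vectors.

    Symmetric in its arguments and always >= 0.  A constant vector has no
    equal-width binning; by default this raises, or returns 0 with
    ``on_constant='zero'``.
    """
    if spec is None:
        spec = HistogramSpec()
    if n_bins is not None or base is not None or on_constant is not None:
        spec = HistogramSpec(
            n_bins=n_bins if n_bins is not None else spec.n_bins,
            base=base if base is not None else spec.base,
            on_constant=on_constant if on_constant is not None else spec.on_constant,
        )
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise InputError("need at least 2 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("inputs contain non-finite values")
    b = spec.resolve_bins(x.size)
    ix = _bin_indices(x, b)
    iy = _bin_indices(y, b)
    if ix is None or iy is None:
        if spec.on_constant == "zero":
            return 0.0
        raise InputError("constant vector: MI undefined under equal-width binning")
    return _convert(_mi_from_indices(ix, iy, b), spec.base)


def column_entropy(x, spec: HistogramSpec | None = None) -> float:
    """Histogram entropy of one variable (equals its self-MI); <= log B."""
    if spec is None:
        spec = HistogramSpec()
    x = np.asarray(x, dtype=float).ravel()
    b = spec.resolve_bins(x.size)
    ix = _bin_indices(x, b)
    if ix is None:
        if spec.on_constant == "zero":
            return 0.0
        raise InputError("constant vector: entropy undefined under equal-width binning")
    p = np.bincount(ix, minlength=b) / ix.size
    p = p[p > 0]
    return _convert(float(-np.sum(p * np.log(p))), spec.base)


def mi_matrix(data, spec: HistogramSpec | None = None, names=None) -> pd.DataFrame:
    """Pairwise MI over all N(N-1)/2 column pairs of a variable matrix.

    The diagonal holds each variable's self-MI (its histogram entropy).
    Returns a symmetric DataFrame indexed by variable name.
    """
    if spec is None:
        spec = HistogramSpec()
    X, names = as_variable_matrix(data, names)
    n_s, n = X.shape
    b = spec.resolve_bins(n_s)
    idx = []
    for j in range(n):
        ij = _bin_indices(X[:, j], b)
        if ij is None and spec.on_constant == "error":
            raise InputError(f"variable {names[j]!r} is constant; MI undefined")
        idx.append(ij)
    M = np.zeros((n, n))
    for j in range(n):
        if idx[j] is None:
            continue
        p = np.bincount(idx[j], minlength=b) / n_s
        p = p[p > 0]
        M[j, j] = -np.sum(p * np.log(p))
    for i in range(n):
        for j in range(i + 1, n):
            if idx[i] is None or idx[j] is None:
                v = 0.0
            else:
                v = _mi_from_indices(idx[i], idx[j], b)
            M[i, j] = M[j, i] = v
    if spec.base == "bits":
        M /= _LN2
    return pd.DataFrame(M, index=names, columns=names)


def dissimilarity_from_mi(mi, delta_max: float = DEFAULT_DELTA_MAX) -> pd.DataFrame:
    """Reciprocal-MI dissimilarity: delta_ij = min(1/MI_ij, delta_max), diag 0."""
    if delta_max <= 0:
        raise InputError("delta_max must be positive")
    names = list(mi.index) if isinstance(mi, pd.DataFrame) else None
    M = check_square_symmetric(mi, "MI matrix")
    if np.any(M < -1e-12):
        raise InputError("MI matrix has negative entries")
    M = np.maximum(M, 0.0)
    with np.errstate(divide="ignore"):
        delta = np.where(M > 0, 1.0 / np.maximum(M, 1e-300), np.inf)
    delta = np.minimum(delta, delta_max)
    np.fill_diagonal(delta, 0.0)
    if names is None:
        names = [f"v{i + 1}" for i in range(M.shape[0])]
    return pd.DataFrame(delta, index=names, columns=names)


class MutualInformationDissimilarity(BaseEstimator):
    """Estimator computing the pairwise-MI and reciprocal-MI matrices.

    Parameters
    ----------
    n_bins : int or None
        Histogram bins per axis; None derives B from the sample size.
    delta_max : float or 'auto'
        Cap on 1/MI.  'auto' (default) caps at the reciprocal of the
        independence bias (B-1)^2/(2 N_s), bounded above by 1e3, so that
        pairs whose MI is indistinguishable from the independence noise
        floor all sit at the same maximal distance.
    base : {'nats', 'bits'}
        Logarithm base for MI (only rescales the dissimilarities uniformly).
    on_constant : {'error', 'zero'}
        How to treat constant variables.

    Attributes
    ----------
    names_ : list of str
    n_bins_ : int
        The bin count actually used.
    mi_matrix_ : DataFrame of shape (N, N)
    dissimilarity_ : DataFrame of shape (N, N)
    """

    def __init__(self, n_bins=None, delta_max="auto",
                 base="nats", on_constant="error"):
        self.n_bins = n_bins
        self.delta_max = delta_max
        self.base = base
        self.on_constant = on_constant

    def _spec(self) -> HistogramSpec:
        return HistogramSpec(n_bins=self.n_bins, base=self.base,
                             on_constant=self.on_constant)

    def fit(self, X, y=None):
        X_arr, names = as_variable_matrix(X)
        spec = self._spec()
        self.names_ = names
        self.n_bins_ = spec.resolve_bins(X_arr.shape[0])
        self.mi_matrix_ = mi_matrix(X_arr, spec, names=names)
        if self.delta_max == "auto":
            self.delta_max_ = auto_delta_max(X_arr.shape[0], self.n_bins_)
        else:
            self.delta_max_ = float(self.delta_max)
        self.dissimilarity_ = dissimilarity_from_mi(self.mi_matrix_, self.delta_max_)
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the dissimilarity matrix as a DataFrame."""
        return self.fit(X).dissimilarity_
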