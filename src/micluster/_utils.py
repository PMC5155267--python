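"""Shared input validation helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Invalid user-supplied data (shape, missing values, bad labels)."""


class NumericalError(RuntimeError):
    """A numerical step failed (no positive eigenvalue, non-PD prior, ...)."""


def as_variable_matrix(data, names=None, min_samples: int = 2, min_variables: int = 2):
    """Coerce a samples x variables table to ``(ndarray, names)``.

    Accepts a pandas DataFrame (column labels become the variable names) or a
    2-D array. Rejects missing/non-finite values; variables are columns.
    """
    if isinstance(data, pd.DataFrame):
        if names is None:
            names = [str(c) for c in data.columns]
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise InputError(f"expected a 2-D samples x variables matrix, got ndim={X.ndim}")
    n_s, n = X.shape
    if n_s < min_samples:
        raise InputError(f"need at least {min_samples} samples, got {n_s}")
    if n < min_variables:
        raise InputError(f"need at least {min_variables} variables, got {n}")
    if not np.all(np.isfinite(X)):
        raise InputError("matrix contains missing or non-finite values; impute first")
    if names is None:
        names = [f"v{i + 1}" for i in range(n)]
    names = [str(v) for v in names]
    if len(names) != n:
        raise InputError(f"{len(names)} names for {n} variables")
    if len(set(names)) != n:
        raise InputError("variable names must be unique")
    return X, names


def check_square_symmetric(M, name: str = "matrix", tol: float = 1e-8):
    """Validate and symmetrize an N x N matrix; returns a float ndarray."""
    A = np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InputError(f"{name} must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise InputError(f"{name} contains non-finite entries")
    if not np.allclose(A, A.T, atol=tol, rtol=tol):
        raise InputError(f"{name} is not symmetric")
    return (A + A.T) / 2.0


def check_binary(z, name: str = "response") -> np.ndarray:
    z = np.asarray(z)
    if z.size == 0:
        raise InputError(f"{name} is empty")
    zf = z.astype(float).ravel()
    if not np.all(np.isin(zf, (0.0, 1.0))):
        raise InputError(f"{name} must contain only 0/1 values")
    return zf.astype(int)
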