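"""Synthetic benchmark generators for variable clustering.

Every generator is a pure function of its parameters and seed and returns a
:class:`SimulatedDataset` carrying the data matrix, the ground-truth variable
partition, an optional binary response, and full provenance.

Generators
----------
``simulate_table1``
    The 20-variable, four-cluster benchmark: two clusters of deterministic
    nonlinear transforms of independent standard normals, one cluster of
    lagged copies of a chaotic logistic-map series (rate 3.8), and one
    cluster of lagged copies of an AR(2) series nonlinearly coupled to the
    x-component of a Lorenz system integrated at dt = 0.01.
``simulate_motivating``
    The small 8-variable example: two independent generators, each with one
    linear-plus-noise copy and two purely nonlinear transforms (square,
    absolute value).  Linear correlation finds the linear copies but misses
    the nonlinear ones; mutual information finds both.
``simulate_blobs``
    Isotropic Gaussian blobs in embedding space (clustering fixtures).
``simulate_vcg_like``
    A grouped-feature surrogate for parameter matrices extracted from
    vectorcardiogram recordings: blocks of mutually redundant features
    (noisy linear copies and absolute-value distortions of a latent factor
    per block, emulating weight vs |weight| redundancy) plus a binary
    outcome from a logistic model on a sparse subset of the factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import InputError
from .dpmm import Partition

__all__ = ["SimulatedDataset", "logistic_map", "lorenz_x", "simulate_table1",
           "simulate_motivating", "simulate_blobs", "simulate_vcg_like"]


@dataclass
class SimulatedDataset:
    """A generated variable matrix with ground truth and provenance."""

    data: pd.DataFrame
    true_labels: Partition
    response: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


def logistic_map(n: int, rate: float = 3.8, x0: float | None = None,
                 burn_in: int = 100, rng: np.random.Generator | None = None) -> np.ndarray:
    """Iterate x <- rate * x * (1 - x); x0 drawn uniform(0.1, 0.9) if None.

    For rate in the chaotic regime and x0 in (0, 1) the orbit stays in (0, 1).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if x0 is None:
        x0 = float(rng.uniform(0.1, 0.9))
    if not 0.0 < x0 < 1.0:
        raise InputError("x0 must lie in (0, 1)")
    x = x0
    for _ in range(burn_in):
        x = rate * x * (1.0 - x)
    out = np.empty(n)
    for i in range(n):
        x = rate * x * (1.0 - x)
        out[i] = x
    return out


def lorenz_x(n: int, dt: float = 0.01, sigma: float = 10.0, rho: float = 28.0,
             beta: float = 8.0 / 3.0, burn_in: int = 1000,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """x-component of the Lorenz system, fixed-step 4th-order Runge-Kutta.

    The initial state is perturbed randomly so independent seeds land on
    different stretches of the attractor; ``burn_in`` steps are discarded.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    state = np.array([1.0, 1.0, 1.0]) + 0.1 * rng.standard_normal(3)

    def f(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    def step(s):
        k1 = f(s)
        k2 = f(s + 0.5 * dt * k1)
        k3 = f(s + 0.5 * dt * k2)
        k4 = f(s + dt * k3)
        return s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    for _ in range(burn_in):
        state = step(state)
    out = np.empty(n)
    for i in range(n):
        state = step(state)
        out[i] = state[0]
    return out


def _lagged_columns(series: np.ndarray, lags, n: int) -> list[np.ndarray]:
    """Columns series[lag : lag + n] for each lag (series must be long enough)."""
    return [series[lag:lag + n] for lag in lags]


def simulate_table1(n: int = 1000, seed: int = 0) -> SimulatedDataset:
    """The 20-variable / 4-cluster benchmark (n samples per variable).

    Cluster 1: v1 ~ N(0,1); v2 = |v1|; v3 = v1^2; v4 = v1^3; v5 = sin(v1).
    Cluster 2: the same construction from an independent v6.
    Cluster 3: v11 from the logistic map at rate 3.8; v12..v15 are the same
    orbit shifted forward by 3, 5, 7 and 9 steps.
    Cluster 4: v16(t) = 0.5 v16(t-1) - 0.3 v16(t-2) + 0.1 x_Lorenz(t)^2 + eps,
    eps ~ N(0, 0.01); v17..v20 shifted forward by 10, 20, 30 and 40 steps.
    All columns are trimmed to the shared length n.
    """
    if n < 100:
        raise InputError("n must be >= 100")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}

    for base, name0 in ((rng.standard_normal(n), "v1"),
                        (rng.standard_normal(n), "v6")):
        i0 = int(name0[1:])
        cols[f"v{i0}"] = base
        cols[f"v{i0 + 1}"] = np.abs(base)
        cols[f"v{i0 + 2}"] = base ** 2
        cols[f"v{i0 + 3}"] = base ** 3
        cols[f"v{i0 + 4}"] = np.sin(base)

    lags3 = (0, 3, 5, 7, 9)
    s3 = logistic_map(n + max(lags3), rng=rng)
    for j, col in enumerate(_lagged_columns(s3, lags3, n)):
        cols[f"v{11 + j}"] = col

    lags4 = (0, 10, 20, 30, 40)
    m4 = n + max(lags4)
    x = lorenz_x(m4, rng=rng)
    eps = 0.1 * rng.standard_normal(m4)
    v16 = np.zeros(m4)
    for t in range(m4):
        v16[t] = (0.5 * (v16[t - 1] if t >= 1 else 0.0)
                  - 0.3 * (v16[t - 2] if t >= 2 else 0.0)
                  + 0.1 * x[t] ** 2 + eps[t])
    for j, col in enumerate(_lagged_columns(v16, lags4, n)):
        cols[f"v{16 + j}"] = col

    names = [f"v{i}" for i in range(1, 21)]
    data = pd.DataFrame({k: cols[k] for k in names})
    labels = Partition(np.repeat(np.arange(4), 5))
    return SimulatedDataset(data=data, true_labels=labels,
                            provenance={"generator": "table1", "n": n, "seed": seed})


def simulate_motivating(n: int = 1000, seed: int = 0) -> SimulatedDataset:
    """The 8-variable / 2-cluster example defeating correlation-based HC.

    v1, v5 ~ N(0,1) independent; v2 = v1 + 0.3 eps (linear, |corr| > 0.9);
    v3 = v1^2 and v4 = |v1| (nonlinear, near-zero correlation with v1);
    v6..v8 mirror the construction from v5.
    """
    if n < 100:
        raise InputError("n must be >= 100")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for base_idx in (1, 5):
        v = rng.standard_normal(n)
        cols[f"v{base_idx}"] = v
        cols[f"v{base_idx + 1}"] = v + 0.3 * rng.standard_normal(n)
        cols[f"v{base_idx + 2}"] = v ** 2
        cols[f"v{base_idx + 3}"] = np.abs(v)
    names = [f"v{i}" for i in range(1, 9)]
    data = pd.DataFrame({k: cols[k] for k in names})
    labels = Partition(np.repeat([0, 1], 4))
    return SimulatedDataset(data=data, true_labels=labels,
                            provenance={"generator": "motivating", "n": n,
                                        "seed": seed})


def simulate_blobs(n_clusters: int = 4, per_cluster: int = 10,
                   separation: float = 20.0, n_features: int = 2,
                   spread: float = 1.0, seed: int = 0):
    """Isotropic Gaussian blobs with the given minimum center separation.

    Centers sit on a circle (first two coordinates) whose radius makes the
    smallest chord equal to ``separation``.  Returns ``(Y, Partition)``.
    """
    if n_clusters < 1 or per_cluster < 1 or n_features < 1:
        raise InputError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_clusters, n_features))
    if n_clusters > 1:
        radius = separation / (2.0 * np.sin(np.pi / n_clusters))
        ang = 2.0 * np.pi * np.arange(n_clusters) / n_clusters
        centers[:, 0] = radius * np.cos(ang)
        centers[:, 1 % n_features] = radius * np.sin(ang)
    labels = np.repeat(np.arange(n_clusters), per_cluster)
    Y = centers[labels] + spread * rng.standard_normal((labels.size, n_features))
    return Y, Partition(labels)


def simulate_vcg_like(n_subjects: int = 300, n_groups: int = 6,
                      group_size: int = 6, effect: float = 1.0,
                      n_active: int = 3, noise_sd: float = 0.3,
                      intercept: float = 0.0, seed: int = 0) -> SimulatedDataset:
    """Grouped redundant features with a logistic binary outcome.

    Each group g has a latent standard-normal factor f_g per subject; its
    features alternate between noisy linear copies (f_g + noise) and noisy
    absolute-value distortions (|f_g| + noise), emulating the weight /
    absolute-weight redundancy of basis-function parameter matrices.  The
    response is Bernoulli with logit = intercept + effect * sum of the first
    ``n_active`` factors with alternating signs.
    """
    if min(n_subjects, n_groups, group_size) < 1:
        raise InputError("sizes must be >= 1")
    if not 0 <= n_active <= n_groups:
        raise InputError("n_active must be in [0, n_groups]")
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n_subjects, n_groups))
    cols = {}
    labels = []
    for g in range(n_groups):
        f = F[:, g]
        for j in range(group_size):
            base = f if j % 2 == 0 else np.abs(f)
            cols[f"g{g + 1}_x{j + 1}"] = base + noise_sd * rng.standard_normal(n_subjects)
            labels.append(g)
    signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n_active)])
    eta = intercept + effect * (F[:, :n_active] @ signs)
    z = (rng.random(n_subjects) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    data = pd.DataFrame(cols)
    return SimulatedDataset(data=data, true_labels=Partition(np.array(labels)),
                            response=z,
                            provenance={"generator": "vcg_like",
                                        "n_subjects": n_subjects,
                                        "n_groups": n_groups,
                                        "group_size": group_size,
                                        "effect": effect, "n_active": n_active,
                                        "noise_sd": noise_sd,
                                        "intercept": intercept, "seed": seed})
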