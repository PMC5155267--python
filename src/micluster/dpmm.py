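"""Dirichlet-process Gaussian mixture clustering by collapsed Gibbs sampling.

The embedded variables (rows of the MDS coordinate matrix Y) are clustered
with a Dirichlet-process mixture of multivariate Gaussians.  The partition
prior is the Chinese Restaurant Process: customer n joins an occupied table k
with probability m_k / (n - 1 + alpha) and opens a new table with probability
alpha / (n - 1 + alpha).  Component means and covariances are integrated out
under a conjugate Normal-Inverse-Wishart base measure, so each Gibbs update
resamples one indicator from

    p(c_n = k | ...) prop. m_{-n,k} * t_k(y_n)        (occupied cluster)
    p(c_n = new | ...) prop. alpha  * t_0(y_n)        (new cluster)

where t_k is the multivariate Student-t posterior predictive of cluster k
with point n removed, and t_0 the prior predictive (Neal's Algorithm 3).

The NIW defaults are empirical-Bayes: m0 = mean(Y), kappa0 = 0.01,
nu0 = d + 2, Psi0 = cov(Y) (+ tiny ridge so it stays positive definite).
A small kappa0 keeps the prior mean weak; Psi0 = cov(Y) sets the scale of a
freshly opened cluster to the overall spread of the data.

The point estimate reported is the maximum-a-posteriori partition over the
post-burn-in trace, scored by the exact joint log posterior
(CRP partition probability x product of per-cluster NIW marginal
likelihoods), which is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, multigammaln
from sklearn.base import BaseEstimator, ClusterMixin

from ._utils import InputError, NumericalError

__all__ = ["NIWPrior", "DPConfig", "Partition", "DPPosterior", "default_prior",
           "crp_assignment_probs", "expected_crp_tables", "gibbs_sweep",
           "fit_dpmm", "DirichletProcessMixture"]


# ---------------------------------------------------------------------------
# priors and configuration

@dataclass(frozen=True)
class NIWPrior:
    """Normal-Inverse-Wishart base measure (m0, kappa0, nu0, Psi0)."""

    m0: np.ndarray
    kappa0: float
    nu0: float
    psi0: np.ndarray

    def validate(self, d: int) -> None:
        m0 = np.asarray(self.m0, dtype=float)
        psi0 = np.asarray(self.psi0, dtype=float)
        if m0.shape != (d,):
            raise InputError(f"m0 must have shape ({d},), got {m0.shape}")
        if self.kappa0 <= 0:
            raise InputError("kappa0 must be positive")
        if self.nu0 <= d - 1:
            raise InputError(f"nu0 must exceed d - 1 = {d - 1}")
        if psi0.shape != (d, d):
            raise InputError(f"Psi0 must have shape ({d}, {d})")
        try:
            np.linalg.cholesky(psi0)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("Psi0 is not positive definite") from exc


DEFAULT_SCALE_FRAC = 0.05


def default_prior(Y: np.ndarray, kappa0: float = 0.01,
                  scale_frac: float = DEFAULT_SCALE_FRAC) -> NIWPrior:
    """Empirical-Bayes NIW prior with an isotropic scale matrix.

    m0 = mean(Y); Psi0 = scale_frac * (tr cov(Y) / d) * I.  With nu0 = d + 2
    the prior expected component covariance equals Psi0, i.e. a fresh
    cluster is expected to occupy ``scale_frac`` of the total variance —
    clusters tight relative to the overall configuration.  The isotropic
    form avoids the pathology of a full cov(Y) scale matrix, whose dominant
    axis is the *between*-cluster separation: that makes the prior
    needle-shaped, so mild within-cluster outliers along the tight axis get
    peeled off into cheap heavy-tailed singletons.

    Degenerate data (zero total variance, e.g. identical rows) falls back
    to the identity scale.
    """
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    m0 = Y.mean(axis=0)
    total_var = float(Y.var(axis=0, ddof=1 if n > 1 else 0).sum()) if n > 1 else 0.0
    scale = scale_frac * total_var / d
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0
    return NIWPrior(m0=m0, kappa0=kappa0, nu0=float(d + 2),
                    psi0=scale * np.eye(d))


@dataclass
class DPConfig:
    """Sampler configuration: concentration, sweeps, burn-in, seed, prior."""

    alpha: float = 1.0
    n_sweeps: int = 1000
    burn_in: int = 200
    seed: int = 0
    prior: NIWPrior | None = None
    sample_alpha: bool = False  # Escobar-West Gamma(1,1) resampling of alpha
    init: str = "single"        # or "perpoint": one cluster per point

    def __post_init__(self):
        if self.alpha <= 0:
            raise InputError("alpha must be positive")
        if self.n_sweeps < 1:
            raise InputError("n_sweeps must be >= 1")
        if not 0 <= self.burn_in < self.n_sweeps:
            raise InputError("need 0 <= burn_in < n_sweeps")
        if self.init not in ("single", "perpoint"):
            raise InputError("init must be 'single' or 'perpoint'")


# ---------------------------------------------------------------------------
# partitions

@dataclass
class Partition:
    """Cluster labels with contiguous ids 0..K-1."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise InputError("labels must be a non-empty 1-D integer vector")
        k = self.labels.max() + 1
        if self.labels.min() < 0 or len(np.unique(self.labels)) != k:
            raise InputError("labels must use contiguous cluster ids 0..K-1")

    @classmethod
    def from_labels(cls, labels) -> "Partition":
        """Normalize arbitrary labels to contiguous ids by first appearance."""
        labels = np.asarray(labels)
        seen: dict = {}
        out = np.empty(labels.size, dtype=int)
        for i, v in enumerate(labels.ravel()):
            out[i] = seen.setdefault(v, len(seen))
        return cls(out)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


@dataclass
class DPPosterior:
    """Post-burn-in Gibbs trace with MAP point estimate and co-clustering."""

    trace: list = field(default_factory=list)           # list[Partition]
    log_posteriors: np.ndarray = None
    map_partition: Partition = None
    cosim: np.ndarray = None                            # co-clustering freq.
    n_clusters_trace: np.ndarray = None                 # K per sweep (all sweeps)


# ---------------------------------------------------------------------------
# CRP prior

def crp_assignment_probs(sizes, n: int, alpha: float) -> np.ndarray:
    """Seating probabilities for customer ``n`` (1-based) over K tables + new.

    Entry k is m_k / (n - 1 + alpha); the last entry is
    alpha / (n - 1 + alpha).
    """
    sizes = np.asarray(sizes, dtype=float)
    if alpha <= 0:
        raise InputError("alpha must be positive")
    if n < 1:
        raise InputError("customer index must be >= 1")
    if sizes.size and np.any(sizes <= 0):
        raise InputError("table sizes must be positive")
    if int(sizes.sum()) != n - 1:
        raise InputError(f"table sizes sum to {int(sizes.sum())}, expected {n - 1}")
    return np.append(sizes, alpha) / (n - 1 + alpha)


def expected_crp_tables(n: int, alpha: float) -> float:
    """E[number of occupied tables after n customers] = sum alpha/(alpha+i-1)."""
    i = np.arange(1, n + 1)
    return float(np.sum(alpha / (alpha + i - 1)))


# ---------------------------------------------------------------------------
# collapsed Gibbs machinery

class _Cluster:
    """Sufficient statistics (n, sum, sum of outer products) with cached
    Student-t posterior-predictive parameters."""

    __slots__ = ("n", "s", "ss", "_pred")

    def __init__(self, d: int):
        self.n = 0
        self.s = np.zeros(d)
        self.ss = np.zeros((d, d))
        self._pred = None

    def add(self, y: np.ndarray) -> None:
        self.n += 1
        self.s += y
        self.ss += np.outer(y, y)
        self._pred = None

    def remove(self, y: np.ndarray) -> None:
        self.n -= 1
        self.s -= y
        self.ss -= np.outer(y, y)
        self._pred = None


def _posterior_niw(prior: NIWPrior, n: int, s: np.ndarray, ss: np.ndarray):
    """NIW posterior (kappa_n, nu_n, m_n, Psi_n) from sufficient statistics."""
    d = s.shape[0]
    kappa_n = prior.kappa0 + n
    nu_n = prior.nu0 + n
    m_n = (prior.kappa0 * np.asarray(prior.m0, float) + s) / kappa_n
    if n > 0:
        ybar = s / n
        S = ss - np.outer(s, s) / n
        dm = ybar - np.asarray(prior.m0, float)
        psi_n = np.asarray(prior.psi0, float) + S + \
            (prior.kappa0 * n / kappa_n) * np.outer(dm, dm)
    else:
        psi_n = np.asarray(prior.psi0, float).copy()
    return kappa_n, nu_n, m_n, (psi_n + psi_n.T) / 2.0


def _pred_params(prior: NIWPrior, cl: _Cluster):
    """Cached Student-t predictive (df, mean, precision, log-normalizer)."""
    if cl._pred is None:
        d = cl.s.shape[0]
        kappa_n, nu_n, m_n, psi_n = _posterior_niw(prior, cl.n, cl.s, cl.ss)
        df = nu_n - d + 1
        scale = psi_n * (kappa_n + 1) / (kappa_n * df)
        sign, logdet = np.linalg.slogdet(scale)
        if sign <= 0:
            raise NumericalError("degenerate predictive covariance")
        prec = np.linalg.inv(scale)
        const = (gammaln((df + d) / 2) - gammaln(df / 2)
                 - 0.5 * d * math.log(df * math.pi) - 0.5 * logdet)
        cl._pred = (df, m_n, prec, const, d)
    return cl._pred


def _log_predictive(params, y: np.ndarray) -> float:
    df, m, prec, const, d = params
    r = y - m
    q = float(r @ prec @ r)
    return const - 0.5 * (df + d) * math.log1p(q / df)


def _log_marginal(prior: NIWPrior, cl: _Cluster) -> float:
    """Log marginal likelihood of one cluster's data under the NIW prior."""
    d = cl.s.shape[0]
    kappa_n, nu_n, _, psi_n = _posterior_niw(prior, cl.n, cl.s, cl.ss)
    _, ld0 = np.linalg.slogdet(np.asarray(prior.psi0, float))
    sign, ldn = np.linalg.slogdet(psi_n)
    if sign <= 0:
        raise NumericalError("degenerate cluster scatter")
    return (-0.5 * cl.n * d * math.log(math.pi)
            + multigammaln(nu_n / 2, d) - multigammaln(prior.nu0 / 2, d)
            + 0.5 * prior.nu0 * ld0 - 0.5 * nu_n * ldn
            + 0.5 * d * (math.log(prior.kappa0) - math.log(kappa_n)))


def _joint_log_posterior(clusters, alpha: float, prior: NIWPrior, n_total: int) -> float:
    """log[CRP(partition) x prod_k marginal likelihood of cluster k]."""
    lp = len(clusters) * math.log(alpha) + gammaln(alpha) - gammaln(alpha + n_total)
    for cl in clusters:
        lp += gammaln(cl.n) + _log_marginal(prior, cl)
    return float(lp)


def _build_state(Y: np.ndarray, labels: np.ndarray):
    k = int(labels.max()) + 1
    clusters = [_Cluster(Y.shape[1]) for _ in range(k)]
    for i, lab in enumerate(labels):
        clusters[lab].add(Y[i])
    return clusters


def _sweep(Y: np.ndarray, labels: np.ndarray, clusters: list, prior: NIWPrior,
           alpha: float, rng: np.random.Generator, empty: _Cluster) -> None:
    """One pass of single-site collapsed Gibbs updates, in index order.

    Empties are deleted immediately and ids compacted, so labels stay
    contiguous throughout.
    """
    n, d = Y.shape
    for i in range(n):
        y = Y[i]
        k = labels[i]
        cl = clusters[k]
        cl.remove(y)
        if cl.n == 0:
            clusters.pop(k)
            labels[labels > k] -= 1
        kk = len(clusters)
        logw = np.empty(kk + 1)
        for j, c in enumerate(clusters):
            logw[j] = math.log(c.n) + _log_predictive(_pred_params(prior, c), y)
        logw[kk] = math.log(alpha) + _log_predictive(_pred_params(prior, empty), y)
        logw -= logw.max()
        w = np.exp(logw)
        cum = np.cumsum(w)
        j = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        j = min(j, kk)
        if j == kk:
            clusters.append(_Cluster(d))
        clusters[j].add(y)
        labels[i] = j


def _resample_alpha(alpha: float, k: int, n: int, rng: np.random.Generator,
                    a: float = 1.0, b: float = 1.0) -> float:
    """Escobar-West auxiliary-variable update under a Gamma(a, b) prior."""
    eta = rng.beta(alpha + 1.0, n)
    rate = b - math.log(eta)
    odds = (a + k - 1) / (n * rate)
    shape = a + k if rng.random() < odds / (1.0 + odds) else a + k - 1
    return float(rng.gamma(shape, 1.0 / rate))


def gibbs_sweep(Y, partition: Partition, cfg: DPConfig,
                rng: np.random.Generator) -> Partition:
    """Resample every indicator once and return the updated partition."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise InputError("Y must be 2-D (variables x embedding dims)")
    labels = np.asarray(partition.labels, dtype=int).copy()
    if labels.size != Y.shape[0]:
        raise InputError("partition size does not match Y")
    prior = cfg.prior if cfg.prior is not None else default_prior(Y)
    prior.validate(Y.shape[1])
    clusters = _build_state(Y, labels)
    empty = _Cluster(Y.shape[1])
    _sweep(Y, labels, clusters, prior, cfg.alpha, rng, empty)
    return Partition(labels)


def fit_dpmm(Y, cfg: DPConfig | None = None, **kwargs) -> DPPosterior:
    """Run the collapsed Gibbs sampler from the all-in-one-cluster start.

    Fully reproducible given ``cfg.seed``.  Returns the post-burn-in trace,
    the MAP partition, and the posterior co-clustering frequency matrix.
    """
    if cfg is None:
        cfg = DPConfig(**kwargs)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 1:
        raise InputError("Y must be a non-empty 2-D array")
    n, d = Y.shape
    prior = cfg.prior if cfg.prior is not None else default_prior(Y)
    prior.validate(d)
    rng = np.random.default_rng(cfg.seed)

    labels = (np.zeros(n, dtype=int) if cfg.init == "single"
              else np.arange(n, dtype=int))
    clusters = _build_state(Y, labels)
    empty = _Cluster(d)
    alpha = cfg.alpha

    trace: list[Partition] = []
    logposts: list[float] = []
    k_trace = np.empty(cfg.n_sweeps, dtype=int)
    for sweep in range(cfg.n_sweeps):
        _sweep(Y, labels, clusters, prior, alpha, rng, empty)
        if cfg.sample_alpha:
            alpha = _resample_alpha(alpha, len(clusters), n, rng)
        k_trace[sweep] = len(clusters)
        if sweep >= cfg.burn_in:
            lp = _joint_log_posterior(clusters, alpha, prior, n)
            if not np.isfinite(lp):
                raise NumericalError("non-finite joint log posterior")
            trace.append(Partition(labels.copy()))
            logposts.append(lp)

    logposts_arr = np.asarray(logposts)
    map_idx = int(np.argmax(logposts_arr))
    cosim = np.zeros((n, n))
    for part in trace:
        lab = part.labels
        cosim += (lab[:, None] == lab[None, :])
    cosim /= len(trace)
    return DPPosterior(trace=trace, log_posteriors=logposts_arr,
                       map_partition=trace[map_idx], cosim=cosim,
                       n_clusters_trace=k_trace)


class DirichletProcessMixture(BaseEstimator, ClusterMixin):
    """DP Gaussian mixture clusterer (collapsed Gibbs, NIW base measure).

    Parameters
    ----------
    alpha : float, default 1.0
        CRP concentration.
    n_sweeps, burn_in : int
        Gibbs sweeps and discarded initial sweeps.
    random_state : int, default 0
    prior : NIWPrior or None
        None fits the empirical-Bayes default from the data.
    sample_alpha : bool, default False
        Resample alpha under a Gamma(1,1) prior each sweep.

    Attributes
    ----------
    labels_ : ndarray (N,)
        MAP partition labels.
    n_clusters_ : int
    posterior_ : DPPosterior
    """

    def __init__(self, alpha: float = 1.0, n_sweeps: int = 1000,
                 burn_in: int = 200, random_state: int = 0,
                 prior: NIWPrior | None = None, sample_alpha: bool = False):
        self.alpha = alpha
        self.n_sweeps = n_sweeps
        self.burn_in = burn_in
        self.random_state = random_state
        self.prior = prior
        self.sample_alpha = sample_alpha

    def fit(self, X, y=None):
        cfg = DPConfig(alpha=self.alpha, n_sweeps=self.n_sweeps,
                       burn_in=self.burn_in, seed=self.random_state,
                       prior=self.prior, sample_alpha=self.sample_alpha)
        self.posterior_ = fit_dpmm(np.asarray(X, dtype=float), cfg)
        self.labels_ = self.posterior_.map_partition.labels
        self.n_clusters_ = self.posterior_.map_partition.n_clusters
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
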