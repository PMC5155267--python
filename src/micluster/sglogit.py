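"""Group elastic-net logistic regression (sparse-group lasso form).

With the per-cluster orthonormal design W, binary response z and column
groups G_1..G_K (one per variable cluster), the fitted model minimizes

    f(b0, beta) = -l(b0, beta) + gamma * sum_k sqrt(p_k) ||beta_{G_k}||_2
                                + lambda * ||beta||_1

where l is the Bernoulli log likelihood of the logistic model
h = sigmoid(b0 + W beta), p_k = |G_k|, and the intercept is unpenalized.
The group term performs cluster-level selection (a whole block of
orthonormalized variables enters or leaves together); the l1 term adds
within-cluster sparsity.  gamma = 0 reduces to l1-penalized logistic
regression; lambda = 0 to the group lasso.

The solver is proximal gradient descent with backtracking line search on the
smooth part.  The proximal operator of the combined penalty separates per
group into elementwise soft-thresholding (lambda) followed by group
soft-thresholding (gamma sqrt(p_k)) — the standard sparse-group-lasso prox.
Backtracking guarantees a monotonically nonincreasing objective; since the
objective is convex, any two starts reach the same value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from ._utils import InputError, check_binary

__all__ = ["logistic_loglik", "GroupEnetModel", "fit_group_enet",
           "predict_proba", "ClassificationReport", "evaluate",
           "tune_group_enet", "SparseGroupLogistic"]


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def logistic_loglik(beta, intercept, W, z) -> float:
    """Bernoulli log likelihood sum_i [z_i log h_i + (1-z_i) log(1-h_i)]; <= 0."""
    W = np.asarray(W, dtype=float)
    z = check_binary(z)
    beta = np.asarray(beta, dtype=float).ravel()
    if W.shape != (z.size, beta.size):
        raise InputError(f"design shape {W.shape} does not match "
                         f"{z.size} responses x {beta.size} coefficients")
    eta = W @ beta + float(intercept)
    # z*eta - log(1 + e^eta), computed stably
    return float(np.sum(z * eta - np.logaddexp(0.0, eta)))


@dataclass
class GroupEnetModel:
    """Fitted group elastic-net logistic model."""

    beta: np.ndarray
    intercept: float
    gamma: float
    lam: float
    group_index: np.ndarray
    converged: bool
    objective_trace: np.ndarray
    n_iter: int

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "lambda": self.lam,
            "group_index": self.group_index.tolist(),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }


def _groups_from_index(group_index: np.ndarray, p: int):
    group_index = np.asarray(group_index, dtype=int).ravel()
    if group_index.size != p:
        raise InputError("group_index length must equal the number of columns")
    ids = np.unique(group_index)
    return [np.flatnonzero(group_index == g) for g in ids]


def _penalty(beta: np.ndarray, groups, gamma: float, lam: float) -> float:
    pen = lam * np.sum(np.abs(beta))
    for g in groups:
        pen += gamma * np.sqrt(g.size) * np.linalg.norm(beta[g])
    return float(pen)


def _prox(beta: np.ndarray, groups, gamma: float, lam: float,
          t: float) -> np.ndarray:
    out = np.sign(beta) * np.maximum(np.abs(beta) - t * lam, 0.0)
    if gamma > 0:
        for g in groups:
            nrm = np.linalg.norm(out[g])
            thr = t * gamma * np.sqrt(g.size)
            out[g] = 0.0 if nrm <= thr else out[g] * (1.0 - thr / nrm)
    return out


def fit_group_enet(W, z, group_index, gamma: float, lam: float, *,
                   max_iter: int = 5000, tol: float = 1e-8,
                   beta0=None, intercept0: float = 0.0) -> GroupEnetModel:
    """Fit by proximal gradient with backtracking; intercept unpenalized.

    The objective trace is monotonically nonincreasing; ``converged`` is
    False (model still returned) if the relative objective change never
    dropped below ``tol`` within ``max_iter`` iterations.
    """
    W = np.asarray(W, dtype=float)
    z = check_binary(z).astype(float)
    if W.ndim != 2 or W.shape[0] != z.size:
        raise InputError("design/response size mismatch")
    if gamma < 0 or lam < 0:
        raise InputError("penalties must be nonnegative")
    n, p = W.shape
    groups = _groups_from_index(group_index, p)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    b0 = float(intercept0)

    def smooth(bb, b00):
        eta = W @ bb + b00
        return float(np.sum(np.logaddexp(0.0, eta) - z * eta))

    def grad(bb, b00):
        r = _sigmoid(W @ bb + b00) - z
        return W.T @ r, float(np.sum(r))

    # Lipschitz bound for the logistic Hessian: ||[1 W]||_2^2 / 4
    aug_norm = np.linalg.norm(np.column_stack([np.ones(n), W]), 2)
    t = 4.0 / max(aug_norm ** 2, 1e-12)

    g_cur = smooth(beta, b0)
    obj = g_cur + _penalty(beta, groups, gamma, lam)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gb, g0 = grad(beta, b0)
        step = t
        while True:
            beta_new = _prox(beta - step * gb, groups, gamma, lam, step)
            b0_new = b0 - step * g0
            db, d0 = beta_new - beta, b0_new - b0
            g_new = smooth(beta_new, b0_new)
            quad = (g_cur + gb @ db + g0 * d0
                    + (db @ db + d0 * d0) / (2.0 * step))
            if g_new <= quad + 1e-12 * abs(quad):
                break
            step *= 0.5
            if step < 1e-18:
                break
        obj_new = g_new + _penalty(beta_new, groups, gamma, lam)
        if obj_new <= obj:  # guard: keep the trace monotone
            beta, b0, g_cur = beta_new, b0_new, g_new
            rel = (obj - obj_new) / max(1.0, abs(obj))
            obj = obj_new
            trace.append(obj)
            if rel < tol:
                converged = True
                break
        else:
            trace.append(obj)
            converged = True  # prox step no longer improves: at optimum
            break
    return GroupEnetModel(beta=beta, intercept=b0, gamma=float(gamma),
                          lam=float(lam),
                          group_index=np.asarray(group_index, int).ravel(),
                          converged=converged,
                          objective_trace=np.asarray(trace), n_iter=it)


def predict_proba(model: GroupEnetModel, W) -> np.ndarray:
    """Success probabilities sigmoid(b0 + W beta); columns must align with training."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] != model.beta.size:
        raise InputError(f"design has {W.shape[1] if W.ndim == 2 else '?'} columns, "
                         f"model expects {model.beta.size}")
    return _sigmoid(W @ model.beta + model.intercept)


@dataclass
class ClassificationReport:
    """Confusion counts with accuracy/sensitivity/specificity in percent."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / max(self.tp + self.tn + self.fp + self.fn, 1)

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else float("nan")

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "accuracy": round(self.accuracy, 2),
                "sensitivity": round(self.sensitivity, 2),
                "specificity": round(self.specificity, 2)}


def evaluate(pred, z) -> ClassificationReport:
    """Confusion-matrix report of 0/1 predictions against 0/1 truth."""
    pred = check_binary(pred, "predictions")
    z = check_binary(z)
    if pred.size != z.size:
        raise InputError("prediction/response length mismatch")
    tp = int(np.sum((pred == 1) & (z == 1)))
    tn = int(np.sum((pred == 0) & (z == 0)))
    fp = int(np.sum((pred == 1) & (z == 0)))
    fn = int(np.sum((pred == 0) & (z == 1)))
    return ClassificationReport(tp=tp, tn=tn, fp=fp, fn=fn)


def tune_group_enet(W, z, group_index, gamma_grid, lam_grid, *,
                    n_splits: int = 10, seed: int = 0,
                    max_iter: int = 2000, tol: float = 1e-7):
    """Pick (gamma, lambda) by seeded stratified k-fold CV accuracy.

    Grids are scanned from largest to smallest penalty and only a strictly
    better mean accuracy replaces the incumbent, so accuracy ties resolve to
    the sparser model.  Returns ``(gamma, lambda, cv_table)``.
    """
    W = np.asarray(W, dtype=float)
    z = check_binary(z)
    gamma_grid = sorted(set(float(g) for g in gamma_grid), reverse=True)
    lam_grid = sorted(set(float(l) for l in lam_grid), reverse=True)
    n_splits = min(n_splits, int(np.bincount(z).min()))
    if n_splits < 2:
        raise InputError("too few samples of one class for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(W, z))
    best = (None, None, -np.inf)
    table = []
    for gamma, lam in product(gamma_grid, lam_grid):
        accs = []
        for tr, te in folds:
            m = fit_group_enet(W[tr], z[tr], group_index, gamma, lam,
                               max_iter=max_iter, tol=tol)
            pred = (predict_proba(m, W[te]) >= 0.5).astype(int)
            accs.append(np.mean(pred == z[te]))
        mean_acc = float(np.mean(accs))
        table.append({"gamma": gamma, "lambda": lam, "cv_accuracy": mean_acc})
        if mean_acc > best[2]:
            best = (gamma, lam, mean_acc)
    return best[0], best[1], table


class SparseGroupLogistic(BaseEstimator, ClassifierMixin):
    """Group elastic-net logistic classifier (sklearn API).

    Parameters
    ----------
    gamma : float
        Group-penalty weight (each group weighted by sqrt of its size).
    lam : float
        Elementwise l1 weight.
    groups : array-like or None
        Column -> group map; None treats every column as its own group.
    max_iter, tol : solver controls.

    Attributes
    ----------
    coef_ : ndarray (p,)
    intercept_ : float
    converged_ : bool
    model_ : GroupEnetModel
    """

    def __init__(self, gamma: float = 0.0, lam: float = 0.0, groups=None,
                 max_iter: int = 5000, tol: float = 1e-8):
        self.gamma = gamma
        self.lam = lam
        self.groups = groups
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = check_binary(y)
        groups = (np.arange(X.shape[1]) if self.groups is None
                  else np.asarray(self.groups, int))
        self.model_ = fit_group_enet(X, y, groups, self.gamma, self.lam,
                                     max_iter=self.max_iter, tol=self.tol)
        self.coef_ = self.model_.beta
        self.intercept_ = self.model_.intercept
        self.converged_ = self.model_.converged
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p1 = predict_proba(self.model_, X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (predict_proba(self.model_, X) >= 0.5).astype(int)
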