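"""End-to-end orchestration: data -> MI -> embedding -> DP clustering ->
per-cluster orthonormalization -> group elastic-net -> report.

:class:`VariableClusteringPipeline` is the in-memory estimator;
:func:`run_pipeline` is the file-based runner behind the command line,
writing every stage artifact (matrices, labels, model, report, config echo,
log) into a run directory with content hashes so a run is reproducible and
auditable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from ._utils import InputError, as_variable_matrix, check_binary
from .dpmm import DPConfig, fit_dpmm
from .gso import orthonormalize_clusters
from .mds import classical_mds
from .mi import HistogramSpec, auto_delta_max, dissimilarity_from_mi, mi_matrix
from .sglogit import evaluate, fit_group_enet, predict_proba, tune_group_enet

__all__ = ["PipelineConfig", "VariableClusteringPipeline", "run_pipeline"]

DEFAULT_GAMMA_GRID = (4.0, 2.0, 1.0, 0.5, 0.1)
DEFAULT_LAM_GRID = (1.0, 0.1, 0.01)


@dataclass
class PipelineConfig:
    """All stage parameters with their module defaults; unknown keys rejected."""

    n_bins: int | None = None
    delta_max: float | str = "auto"
    mi_base: str = "nats"
    on_constant: str = "error"
    n_components: int = 2
    dim_auto: bool = False
    alpha: float = 1.0
    n_sweeps: int = 1000
    burn_in: int = 200
    sample_alpha: bool = False
    gso_tol: float = 1e-8
    gso_center: bool = True
    gso_order: str = "input"
    gamma: float | None = None
    lam: float | None = None
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    lam_grid: tuple = DEFAULT_LAM_GRID
    cv_folds: int = 10
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["gamma_grid"] = list(self.gamma_grid)
        out["lam_grid"] = list(self.lam_grid)
        return out


class VariableClusteringPipeline(BaseEstimator):
    """MI -> classical scaling -> DP mixture (and optionally GSO + group
    elastic-net when a binary response is supplied).

    ``fit(X)`` clusters the columns of X; ``fit(X, z)`` additionally fits the
    predictive model on the cluster-orthonormalized design.  Penalties left
    at None are tuned by seeded stratified CV accuracy over the grids.

    Attributes (after fit)
    ----------------------
    mi_matrix_, dissimilarity_ : DataFrame (N, N)
    embedding_ : ndarray (N, d)
    labels_ : ndarray (N,) — MAP partition of the variables
    n_clusters_ : int
    posterior_ : DPPosterior
    blocks_, group_index_, model_, train_report_ : predictive stage
    """

    def __init__(self, n_bins=None, delta_max="auto", mi_base: str = "nats",
                 on_constant: str = "error", n_components: int = 2,
                 dim_auto: bool = False, alpha: float = 1.0,
                 n_sweeps: int = 1000, burn_in: int = 200,
                 sample_alpha: bool = False, gso_tol: float = 1e-8,
                 gso_center: bool = True, gso_order: str = "input",
                 gamma=None, lam=None, gamma_grid=DEFAULT_GAMMA_GRID,
                 lam_grid=DEFAULT_LAM_GRID, cv_folds: int = 10,
                 random_state: int = 0):
        self.n_bins = n_bins
        self.delta_max = delta_max
        self.mi_base = mi_base
        self.on_constant = on_constant
        self.n_components = n_components
        self.dim_auto = dim_auto
        self.alpha = alpha
        self.n_sweeps = n_sweeps
        self.burn_in = burn_in
        self.sample_alpha = sample_alpha
        self.gso_tol = gso_tol
        self.gso_center = gso_center
        self.gso_order = gso_order
        self.gamma = gamma
        self.lam = lam
        self.gamma_grid = gamma_grid
        self.lam_grid = lam_grid
        self.cv_folds = cv_folds
        self.random_state = random_state

    # -- clustering stage -------------------------------------------------
    def fit(self, X, y=None):
        X_arr, names = as_variable_matrix(X)
        self.names_ = names
        spec = HistogramSpec(n_bins=self.n_bins, base=self.mi_base,
                             on_constant=self.on_constant)
        self.mi_matrix_ = mi_matrix(X_arr, spec, names=names)
        if self.delta_max == "auto":
            self.delta_max_ = auto_delta_max(X_arr.shape[0],
                                             spec.resolve_bins(X_arr.shape[0]))
        else:
            self.delta_max_ = float(self.delta_max)
        self.dissimilarity_ = dissimilarity_from_mi(self.mi_matrix_, self.delta_max_)
        coords = classical_mds(self.dissimilarity_, self.n_components,
                               self.dim_auto)
        self.coordinates_ = coords
        self.embedding_ = coords.Y
        cfg = DPConfig(alpha=self.alpha, n_sweeps=self.n_sweeps,
                       burn_in=self.burn_in, seed=self.random_state,
                       sample_alpha=self.sample_alpha)
        self.posterior_ = fit_dpmm(self.embedding_, cfg)
        self.labels_ = self.posterior_.map_partition.labels
        self.n_clusters_ = self.posterior_.map_partition.n_clusters

        if y is not None:
            self._fit_predictive(X_arr, names, y)
        return self

    # -- predictive stage -------------------------------------------------
    def _fit_predictive(self, X_arr, names, y):
        z = check_binary(y)
        if z.size != X_arr.shape[0]:
            raise InputError("response length must match the number of samples")
        df = pd.DataFrame(X_arr, columns=names)
        self.blocks_ = orthonormalize_clusters(
            df, self.posterior_.map_partition, tol=self.gso_tol,
            center=self.gso_center, order=self.gso_order)
        W = self.blocks_.W
        groups = self.blocks_.group_index
        self.group_index_ = groups
        gamma, lam = self.gamma, self.lam
        if gamma is None or lam is None:
            g_grid = list(self.gamma_grid) if gamma is None else [gamma]
            l_grid = list(self.lam_grid) if lam is None else [lam]
            gamma, lam, self.cv_table_ = tune_group_enet(
                W, z, groups, g_grid, l_grid, n_splits=self.cv_folds,
                seed=self.random_state)
        self.model_ = fit_group_enet(W, z, groups, gamma, lam)
        pred = (predict_proba(self.model_, W) >= 0.5).astype(int)
        self.train_report_ = evaluate(pred, z)

    def predict_proba(self, X):
        if not hasattr(self, "model_"):
            raise InputError("pipeline was fitted without a response")
        W = self.blocks_.transform(X)
        return predict_proba(self.model_, W)

    def predict(self, X):
        return (self.predict_proba(X) >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# file-based runner

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_table(path, sep: str = ",", header: bool = True) -> pd.DataFrame:
    """Read a delimited samples x variables table."""
    try:
        df = pd.read_csv(path, sep=sep, header=0 if header else None)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    if not header:
        df.columns = [f"v{i + 1}" for i in range(df.shape[1])]
    return df


def run_pipeline(data_path, response_path=None, config: PipelineConfig | None = None,
                 outdir="micluster_run", sep: str = ",", header: bool = True) -> dict:
    """Run every stage on files and write all artifacts to ``outdir``.

    Without a response file the run stops after clustering and no model is
    emitted.  Returns a manifest dict (also written as ``manifest.json``)
    mapping artifact names to paths and content hashes.
    """
    if config is None:
        config = PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    t_start = time.perf_counter()

    def log(stage, msg):
        log_lines.append(f"[{time.perf_counter() - t_start:8.2f}s] {stage}: {msg}")

    df = read_table(data_path, sep=sep, header=header)
    z = None
    if response_path is not None:
        zdf = read_table(response_path, sep=sep, header=header)
        z = check_binary(zdf.iloc[:, 0].to_numpy())
    log("input", f"{df.shape[0]} samples x {df.shape[1]} variables"
        + ("" if z is None else f", response n={z.size}"))

    pipe = VariableClusteringPipeline(
        n_bins=config.n_bins, delta_max=config.delta_max, mi_base=config.mi_base,
        on_constant=config.on_constant, n_components=config.n_components,
        dim_auto=config.dim_auto, alpha=config.alpha, n_sweeps=config.n_sweeps,
        burn_in=config.burn_in, sample_alpha=config.sample_alpha,
        gso_tol=config.gso_tol, gso_center=config.gso_center,
        gso_order=config.gso_order, gamma=config.gamma, lam=config.lam,
        gamma_grid=tuple(config.gamma_grid), lam_grid=tuple(config.lam_grid),
        cv_folds=config.cv_folds, random_state=config.seed)

    stage = "clustering"
    try:
        pipe.fit(df, z)
    except Exception:
        log(stage, "FAILED")
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")
        raise
    log("mi", f"B={HistogramSpec(n_bins=config.n_bins).resolve_bins(df.shape[0])}")
    log("embedding", f"d={pipe.embedding_.shape[1]}, negative eigenvalue mass "
        f"{pipe.coordinates_.negative_eigenvalue_mass:.3f}")
    log("dpmm", f"MAP K={pipe.n_clusters_}")

    paths = {}

    def write_df(name, frame, index=True):
        p = out / name
        frame.to_csv(p, index=index)
        paths[name] = p

    write_df("mi.csv", pipe.mi_matrix_)
    write_df("dissimilarity.csv", pipe.dissimilarity_)
    write_df("embedding.csv", pipe.coordinates_.to_frame())
    write_df("eigenvalues.csv",
             pd.DataFrame({"eigenvalue": pipe.coordinates_.eigenvalues}), index=False)
    write_df("labels.csv", pd.DataFrame({"variable": pipe.names_,
                                         "cluster": pipe.labels_}), index=False)
    write_df("cosim.csv", pd.DataFrame(pipe.posterior_.cosim,
                                       index=pipe.names_, columns=pipe.names_))
    trace_summary = {
        "n_clusters_per_sweep": pipe.posterior_.n_clusters_trace.tolist(),
        "log_posterior": pipe.posterior_.log_posteriors.tolist(),
    }
    (out / "trace.json").write_text(json.dumps(trace_summary))
    paths["trace.json"] = out / "trace.json"

    if z is not None:
        write_df("design.csv", pipe.blocks_.to_frame(), index=False)
        (out / "groups.json").write_text(json.dumps(
            {c: int(g) for c, g in zip(pipe.blocks_.column_names,
                                       pipe.group_index_)}))
        paths["groups.json"] = out / "groups.json"
        model_doc = pipe.model_.to_dict()
        model_doc["column_names"] = pipe.blocks_.column_names
        (out / "model.json").write_text(json.dumps(model_doc))
        paths["model.json"] = out / "model.json"
        rep = pipe.train_report_.to_dict()
        write_df("report.csv", pd.DataFrame([rep]), index=False)
        log("model", f"gamma={pipe.model_.gamma}, lambda={pipe.model_.lam}, "
            f"training accuracy {rep['accuracy']:.2f}%")
    else:
        log("model", "skipped (no response supplied)")

    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    paths["config.yaml"] = out / "config.yaml"
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    paths["log.txt"] = out / "log.txt"

    manifest = {name: {"path": str(p), "sha256": _sha256(Path(p))}
                for name, p in paths.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
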