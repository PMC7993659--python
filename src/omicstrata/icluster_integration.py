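"""Lasso-penalized Gaussian latent-variable integrative clustering.

Joint model over T data types sharing latent positions: for data type t,
``X_t = W_t Z + eps_t`` with diagonal Gaussian noise and standard-Gaussian
latent columns Z of dimension k-1 for k clusters. Fitting is EM: the E-step
computes the posterior mean/covariance of Z given the stacked data (a
(k-1)x(k-1) solve via the Woodbury identity), the M-step updates the loadings
with per-type soft-thresholding (lasso, lambda in [0,1] scaled by the largest
unpenalized update of that type) and the noise variances from residual
moments. Final clusters come from seeded k-means on the posterior latent
means.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from ._stats import logrank_test
from .errors import InvalidConfigError, InvalidInputError, NoSolutionError
from .matrix import OmicsMatrix, SubtypeAssignment

#: Lambda vectors reported for the reference cohort (documented presets, not defaults).
PRESET_LAMBDAS = {
    2: (0.26756757, 0.02432432, 0.29459459),
    3: (0.95945946, 0.01351351, 0.57567568),
}


@dataclass(frozen=True)
class IClusterConfig:
    k: int = 3
    lambdas: tuple[float, ...] = (0.1, 0.1, 0.1)
    n_lambda_points: int = 101
    n_repeats: int = 20
    max_iter: int = 100
    tol: float = 1e-5
    seed: int = 0
    kmeans_restarts: int = 20

    def validate(self, n_types: int) -> None:
        if self.k < 2:
            raise InvalidConfigError("k must be >= 2")
        if len(self.lambdas) != n_types:
            raise InvalidConfigError(f"need one lambda per data type ({n_types})")
        if any(not 0.0 <= l <= 1.0 for l in self.lambdas):
            raise InvalidConfigError("lambdas must lie in [0, 1]")


@dataclass
class IClusterModel:
    loadings: list[np.ndarray]  # per data type, features x (k-1)
    latent: np.ndarray  # (k-1) x n posterior means
    noise_variances: list[np.ndarray]
    log_likelihood_trace: np.ndarray
    converged: bool
    assignment: SubtypeAssignment | None
    config: IClusterConfig
    samples: list[str] = field(default_factory=list)

    @property
    def n_nonzero_loadings(self) -> list[int]:
        return [int(np.count_nonzero(w)) for w in self.loadings]


def standardize_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise mean 0 / sd 1; zero-variance rows become all-zero."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def prepare_layers(
    cnv: OmicsMatrix,
    met: OmicsMatrix,
    expression: OmicsMatrix,
    genes_cnv: set[str] | None = None,
    genes_met: set[str] | None = None,
) -> tuple[list[pd.DataFrame], list[str]]:
    """Restrict layers to their gene sets, transform and row-standardize.

    Beta values are logit-transformed (clipped to [0.001, 0.999]); expression is
    log2(FPKM+1). Returns standardized frames sharing one sample order.
    """
    shared = [s for s in cnv.samples if s in set(met.samples) and s in set(expression.samples)]
    if len(shared) < 3:
        raise InvalidInputError("layers share fewer than 3 samples")

    def _subset(m: OmicsMatrix, genes) -> pd.DataFrame:
        df = m.values[shared]
        if genes is not None:
            df = df.loc[[g for g in df.index if g in genes]]
        return df.dropna(axis=0)

    cnv_df = _subset(cnv, genes_cnv)
    met_df = _subset(met, genes_met)
    union = (genes_cnv | genes_met) if (genes_cnv is not None and genes_met is not None) else None
    expr_df = np.log2(_subset(expression, union) + 1.0)
    beta = np.clip(met_df.to_numpy(dtype=float), 0.001, 0.999)
    met_logit = pd.DataFrame(np.log(beta / (1.0 - beta)), index=met_df.index, columns=shared)

    out = []
    for df in (cnv_df, met_logit, expr_df):
        z = standardize_rows(df.to_numpy(dtype=float))
        keep = z.std(axis=1) > 0
        out.append(pd.DataFrame(z[keep], index=df.index[keep], columns=shared))
    return out, shared


def _stack(data: list[np.ndarray]) -> tuple[np.ndarray, list[slice]]:
    slices, offset = [], 0
    for d in data:
        slices.append(slice(offset, offset + d.shape[0]))
        offset += d.shape[0]
    return np.vstack(data), slices


def fit_icluster(
    data: list[pd.DataFrame] | list[np.ndarray],
    config: IClusterConfig,
) -> IClusterModel:
    """Fit the joint latent-variable model by EM and cluster the latent means."""
    frames = [pd.DataFrame(d) for d in data]
    config.validate(len(frames))
    samples = list(frames[0].columns)
    for f in frames[1:]:
        if list(f.columns) != samples:
            raise InvalidInputError("data types must share identical sample columns")
    mats = [f.to_numpy(dtype=float) for f in frames]
    for m in mats:
        if not np.isfinite(m).all():
            raise InvalidInputError("non-finite values in input data")

    x, slices = _stack(mats)
    p, n = x.shape
    q = config.k - 1
    if q >= n:
        raise InvalidConfigError("k - 1 must be < number of samples")
    rng = np.random.default_rng(config.seed)

    w = rng.normal(0.0, 0.1, size=(p, q))
    psi = np.full(p, 1.0)
    xx_row = (x * x).sum(axis=1)  # per-feature sum of squares, reused every iteration

    def _loglik(w, psi):
        wp = w / psi[:, None]
        m = np.eye(q) + w.T @ wp
        a = wp.T @ x  # q x n
        sign, logdet_m = np.linalg.slogdet(m)
        logdet = logdet_m + np.log(psi).sum()
        minv_a = np.linalg.solve(m, a)
        trace_term = (xx_row / psi).sum() - (a * minv_a).sum()
        return -0.5 * (n * p * np.log(2 * np.pi) + n * logdet + trace_term)

    trace = []
    converged = False
    for _ in range(config.max_iter):
        trace.append(_loglik(w, psi))
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1.0)
            if rel < config.tol:
                converged = True
                break
        # E-step
        wp = w / psi[:, None]
        m = np.eye(q) + w.T @ wp
        sigma_post = np.linalg.inv(m)
        ez = sigma_post @ (wp.T @ x)  # q x n
        s_zz = n * sigma_post + ez @ ez.T

        # M-step: per-type unpenalized solve then soft-threshold
        xez = x @ ez.T  # p x q
        w_unpen = np.linalg.solve(s_zz, xez.T).T
        w_new = w_unpen.copy()
        for sl, lam in zip(slices, config.lambdas):
            if lam > 0:
                block = w_unpen[sl]
                thr = lam * (np.abs(block).max() if block.size else 0.0)
                w_new[sl] = np.sign(block) * np.maximum(np.abs(block) - thr, 0.0)
        w = w_new
        psi = (xx_row - 2.0 * (w * xez).sum(axis=1) + np.einsum("iq,qr,ir->i", w, s_zz, w)) / n
        psi = np.maximum(psi, 1e-6)

    if not converged:
        warnings.warn("EM did not converge within max_iter")

    wp = w / psi[:, None]
    m = np.eye(q) + w.T @ wp
    ez = np.linalg.solve(m, wp.T @ x)

    if np.count_nonzero(w) == 0:
        warnings.warn("all loadings shrunk to zero; model degenerate, assignment undefined")
        assignment = None
    else:
        km = KMeans(
            n_clusters=config.k,
            n_init=config.kmeans_restarts,
            random_state=int(np.random.default_rng(config.seed).integers(2**31)),
        )
        labels = km.fit_predict(ez.T) + 1
        assignment = SubtypeAssignment(
            method=f"icluster-k{config.k}", labels={s: int(l) for s, l in zip(samples, labels)}
        )

    loadings = [w[sl].copy() for sl in slices]
    psis = [psi[sl].copy() for sl in slices]
    return IClusterModel(
        loadings=loadings,
        latent=ez,
        noise_variances=psis,
        log_likelihood_trace=np.asarray(trace),
        converged=converged,
        assignment=assignment,
        config=config,
        samples=samples,
    )


def tune_lambda(
    data,
    k: int,
    n_points: int = 101,
    n_repeats_per_point: int = 1,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> tuple[tuple[float, ...], pd.DataFrame]:
    """Screen lambda vectors from a seeded low-discrepancy design over [0,1]^T.

    Each candidate is fitted ``n_repeats_per_point`` times; selection maximizes
    the mean silhouette of the k-cluster assignment in latent space.
    """
    frames = [pd.DataFrame(d) for d in data]
    n_types = len(frames)
    sampler = qmc.Halton(d=n_types, seed=seed)
    points = sampler.random(n_points)
    rows = []
    for i, lam in enumerate(points):
        sils = []
        for rep in range(n_repeats_per_point):
            cfg = IClusterConfig(
                k=k, lambdas=tuple(float(v) for v in lam),
                max_iter=max_iter, tol=tol, seed=seed * 10_000 + i * 100 + rep,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_icluster(frames, cfg)
            if model.assignment is None or model.assignment.k < 2:
                sils.append(float("-inf"))
            else:
                labels = model.assignment.label_array(model.samples)
                sils.append(float(silhouette_score(model.latent.T, labels)))
        rows.append({
            "point": i,
            **{f"lambda_{t}": float(lam[t]) for t in range(n_types)},
            "mean_silhouette": float(np.mean(sils)),
        })
    diag = pd.DataFrame(rows)
    finite = diag[np.isfinite(diag["mean_silhouette"])]
    if finite.empty:
        raise NoSolutionError("all lambda points degenerate; diagnostics:\n" + diag.to_string())
    best = finite.sort_values(
        ["mean_silhouette", "point"], ascending=[False, True]
    ).iloc[0]
    lambdas = tuple(float(best[f"lambda_{t}"]) for t in range(n_types))
    return lambdas, diag


def stability_repeats(
    data,
    k_values=(2, 3, 4),
    lambdas: tuple[float, ...] | None = None,
    n_repeats: int = 20,
    seed: int = 0,
    clinical: pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> tuple[pd.DataFrame, dict[int, SubtypeAssignment]]:
    """Refit each k with ``n_repeats`` seeds; stability = mean pairwise ARI.

    The representative ("consensus") assignment per k is the refit with maximal
    mean ARI to all other refits. If a clinical table is supplied, the log-rank
    p of that assignment is reported. The report ranks k; the final choice is
    left to the caller.
    """
    frames = [pd.DataFrame(d) for d in data]
    n_types = len(frames)
    rows = []
    consensus: dict[int, SubtypeAssignment] = {}
    for k in k_values:
        lam = lambdas if lambdas is not None else tuple([0.1] * n_types)
        assignments = []
        for rep in range(n_repeats):
            cfg = IClusterConfig(k=k, lambdas=lam, max_iter=max_iter, tol=tol,
                                 seed=seed * 1_000 + k * 100 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_icluster(frames, cfg)
            if model.assignment is not None:
                assignments.append(model.assignment)
        if len(assignments) < 2:
            rows.append({"k": k, "stability": float("nan"), "n_fits": len(assignments),
                         "logrank_p": float("nan")})
            continue
        samples = assignments[0].samples
        label_arrays = [a.label_array(samples) for a in assignments]
        m = len(label_arrays)
        ari = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                ari[i, j] = ari[j, i] = adjusted_rand_score(label_arrays[i], label_arrays[j])
        stability = float(ari[np.triu_indices(m, 1)].mean())
        rep_idx = int(ari.sum(axis=1).argmax())
        consensus[k] = assignments[rep_idx]

        logrank_p = float("nan")
        if clinical is not None:
            shared = [s for s in samples if s in clinical.index]
            labels = consensus[k].label_array(shared)
            if len(set(labels)) > 1:
                _, logrank_p, _ = logrank_test(
                    clinical.loc[shared, "OS_time"].to_numpy(dtype=float),
                    clinical.loc[shared, "OS_event"].to_numpy(dtype=int),
                    labels,
                )
        rows.append({"k": k, "stability": stability, "n_fits": m, "logrank_p": logrank_p})
    return pd.DataFrame(rows), consensus
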