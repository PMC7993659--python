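"""Consensus subtyping by KL-divergence NMF with rank-selection metrics.

The factorization uses the classic multiplicative update rules for the
Kullback-Leibler objective ("brunet" variant): repeated random restarts give a
sample x sample consensus (co-assignment) matrix per rank, from which the
cophenetic correlation coefficient, dispersion index and mean silhouette are
derived. Rank selection maximizes the cophenetic coefficient among ranks whose
smallest cluster meets a minimum size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .errors import InvalidConfigError, InvalidInputError, NoSolutionError
from .matrix import OmicsMatrix, SubtypeAssignment


@dataclass
class NMFModel:
    W: np.ndarray
    H: np.ndarray
    rank: int
    divergence: float
    n_iter: int
    divergence_trace: np.ndarray


@dataclass
class ConsensusResult:
    rank: int
    consensus: pd.DataFrame
    cophenetic: float
    dispersion: float
    mean_silhouette: float
    assignment: SubtypeAssignment
    admissible: bool


def _kl_divergence(v: np.ndarray, wh: np.ndarray) -> float:
    mask = v > 0
    term = np.zeros_like(v)
    term[mask] = v[mask] * np.log(v[mask] / wh[mask])
    return float(term.sum() - v.sum() + wh.sum())


def nmf_factorize(
    v: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFModel:
    """KL-divergence NMF via multiplicative updates from one random start."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0) or not np.isfinite(v).all():
        raise InvalidInputError("NMF input must be non-negative and finite")
    m, n = v.shape
    if rank >= min(m, n):
        raise InvalidConfigError(f"rank {rank} must be < min(matrix dims) = {min(m, n)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(v.mean() / rank) if v.mean() > 0 else 1.0
    w = rng.uniform(0.1, 1.0, size=(m, rank)) * scale
    h = rng.uniform(0.1, 1.0, size=(rank, n)) * scale
    eps = np.finfo(float).tiny

    trace = []
    prev = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        wh = w @ h + eps
        h *= (w.T @ (v / wh)) / np.maximum(w.sum(axis=0)[:, None], eps)
        wh = w @ h + eps
        w *= ((v / wh) @ h.T) / np.maximum(h.sum(axis=1)[None, :], eps)
        div = _kl_divergence(v, w @ h + eps)
        trace.append(div)
        if np.isfinite(prev) and abs(prev - div) <= tol * max(abs(prev), 1.0):
            prev = div
            break
        prev = div
    return NMFModel(w, h, rank, prev, n_iter, np.asarray(trace))


def _hard_labels(model: NMFModel) -> np.ndarray:
    return model.H.argmax(axis=0)


def consensus_cluster(
    v: pd.DataFrame,
    rank: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    min_cluster_size: int = 10,
    method: str = "NMF",
) -> ConsensusResult:
    """Consensus over ``n_runs`` random restarts with stability metrics."""
    samples = list(v.columns)
    x = v.to_numpy(dtype=float)
    n = len(samples)
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    co = np.zeros((n, n))
    for ss in seeds:
        run_seed = int(ss.generate_state(1)[0])
        labels = _hard_labels(nmf_factorize(x, rank, seed=run_seed, max_iter=max_iter, tol=tol))
        same = labels[:, None] == labels[None, :]
        co += same
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = average(condensed)
    labels = fcluster(link, t=rank, criterion="maxclust")

    if np.std(condensed) == 0:
        warnings.warn(f"rank {rank}: constant consensus dissimilarities; cophenetic undefined")
        cpcc = float("nan")
    else:
        coph_dists = cophenet(link)
        if np.std(coph_dists) == 0:
            cpcc = float("nan") if np.std(condensed) > 0 else 1.0
        else:
            cpcc = float(np.corrcoef(coph_dists, condensed)[0, 1])

    dispersion = float(np.mean((2.0 * (consensus - 0.5)) ** 2))
    if len(set(labels)) > 1:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    else:
        sil = float("nan")

    sizes = np.bincount(labels)[1:]
    admissible = bool(len(sizes) == rank and sizes.min() >= min_cluster_size)
    assignment = SubtypeAssignment(
        method=f"{method}-k{rank}", labels={s: int(l) for s, l in zip(samples, labels)}
    )
    return ConsensusResult(
        rank=rank,
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        cophenetic=cpcc,
        dispersion=dispersion,
        mean_silhouette=sil,
        assignment=assignment,
        admissible=admissible,
    )


def select_rank(results: list[ConsensusResult]) -> int:
    """Maximal cophenetic among admissible ranks; ties -> higher silhouette, then smaller rank."""
    admissible = [r for r in results if r.admissible and np.isfinite(r.cophenetic)]
    if not admissible:
        raise NoSolutionError("no admissible rank (cluster-size constraint failed everywhere)")
    best = sorted(admissible, key=lambda r: (-r.cophenetic, -r.mean_silhouette, r.rank))
    return best[0].rank


def metrics_frame(results: list[ConsensusResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [r.rank for r in results],
            "cophenetic": [r.cophenetic for r in results],
            "dispersion": [r.dispersion for r in results],
            "mean_silhouette": [r.mean_silhouette for r in results],
            "min_cluster_size": [min(r.assignment.cluster_sizes().values()) for r in results],
            "admissible": [r.admissible for r in results],
        }
    )


def subtype_overlap(
    a: SubtypeAssignment,
    b: SubtypeAssignment,
    seed: int = 0,
    n_monte_carlo: int = 100_000,
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Contingency of two assignments + chi-square p + row-normalized fractions.

    When any expected count is below 5 the chi-square p is replaced by a seeded
    Monte-Carlo permutation p on the same statistic.
    """
    shared = [s for s in a.samples if s in b.labels]
    if not shared:
        raise InvalidInputError("assignments share no samples")
    la = pd.Series({s: a.labels[s] for s in shared}, name="a")
    lb = pd.Series({s: b.labels[s] for s in shared}, name="b")
    table = pd.crosstab(la, lb)
    obs = table.to_numpy(dtype=float)
    if min(obs.shape) < 2:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, expected = stats.chi2_contingency(obs, correction=(obs.shape == (2, 2)))
        if (expected < 5).any():
            rng = np.random.default_rng(seed)
            _, ia = np.unique(la.to_numpy(), return_inverse=True)
            _, ib = np.unique(lb.to_numpy(), return_inverse=True)
            ka, kb = ia.max() + 1, ib.max() + 1
            # uncorrected Pearson statistic for both observed and permuted tables
            def _chi2(ix, iy):
                t = np.bincount(ix * kb + iy, minlength=ka * kb).reshape(ka, kb).astype(float)
                exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
                with np.errstate(invalid="ignore", divide="ignore"):
                    terms = (t - exp) ** 2 / exp
                return np.nansum(terms[exp > 0])

            observed_stat = _chi2(ia, ib)
            count = 0
            for _ in range(n_monte_carlo):
                if _chi2(ia, rng.permutation(ib)) >= observed_stat - 1e-12:
                    count += 1
            p = (count + 1) / (n_monte_carlo + 1)
    fractions = table.div(table.sum(axis=1), axis=0)
    return table, float(p), fractions
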