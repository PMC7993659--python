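"""Correlation-based gene screens and the univariate prognostic screen.

Per gene, the Pearson correlation between an omics layer (gene-level CNV
log-ratios or promoter methylation) and log2(FPKM+1) expression is computed,
Fisher-transformed (z = ln((1+r)/(1-r))) and tested with the t transform on
n-2 degrees of freedom. Genes passing p < 1e-5 form the layer's gene set
(CNV-G or MET-G). The prognostic screen median-splits the cohort on each
gene's expression and applies a two-group log-rank test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import fisher_z, logrank_test, rowwise_pearson
from .errors import InvalidInputError
from .matrix import OmicsMatrix

LAYERS = ("cnv", "met")


@dataclass(frozen=True)
class GeneOmicsCorrelation:
    gene: str
    layer: str
    r: float
    z: float
    p: float
    n: int


@dataclass(frozen=True)
class PrognosticRecord:
    gene: str
    logrank_statistic: float
    p: float
    direction: str  # adverse | favorable
    grouping: str


def log_expression(expression: OmicsMatrix) -> pd.DataFrame:
    """log2(FPKM + 1); the expression scale used for correlation and clustering."""
    if expression.kind != "fpkm":
        raise InvalidInputError("expected an FPKM matrix")
    return np.log2(expression.values + 1.0)


def correlate_omics_expression(
    omics: OmicsMatrix,
    expression: OmicsMatrix,
    layer: str,
) -> list[GeneOmicsCorrelation]:
    """Per-gene Pearson r, Fisher z and p between an omics layer and expression."""
    if layer not in LAYERS:
        raise InvalidInputError(f"layer must be one of {LAYERS}")
    expr = log_expression(expression)
    genes = [g for g in omics.genes if g in set(expr.index)]
    samples = [s for s in omics.samples if s in set(expr.columns)]
    if not genes or not samples:
        raise InvalidInputError("omics and expression share no genes/samples")

    a = omics.values.loc[genes, samples].to_numpy(dtype=float)
    b = expr.loc[genes, samples].to_numpy(dtype=float)
    complete = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1)

    out: list[GeneOmicsCorrelation] = []
    if complete.any():
        r_all, p_all = rowwise_pearson(a[complete], b[complete])
        z_all = fisher_z(r_all)
        comp_genes = [g for g, ok in zip(genes, complete) if ok]
        out.extend(
            GeneOmicsCorrelation(g, layer, float(r), float(z), float(p), len(samples))
            for g, r, z, p in zip(comp_genes, r_all, z_all, p_all)
        )
    # genes with missing entries fall back to pairwise-complete correlation
    from ._stats import pearson_with_p

    for i, g in enumerate(genes):
        if complete[i]:
            continue
        r, p, n = pearson_with_p(a[i], b[i])
        if n < 3 or not np.isfinite(r):
            continue
        out.append(GeneOmicsCorrelation(g, layer, r, float(fisher_z(r)), p, n))
    return out


def select_correlated_genes(
    records: list[GeneOmicsCorrelation], alpha: float = 1e-5
) -> set[str]:
    """Genes with p strictly below alpha, any correlation sign."""
    return {rec.gene for rec in records if np.isfinite(rec.p) and rec.p < alpha}


def correlation_frame(records: list[GeneOmicsCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "layer": [r.layer for r in records],
            "r": [r.r for r in records],
            "z": [r.z for r in records],
            "p": [r.p for r in records],
            "n": [r.n for r in records],
        }
    )


def prognostic_screen(
    expression: OmicsMatrix,
    clinical: pd.DataFrame,
    genes: set[str] | None = None,
    alpha: float = 0.05,
) -> list[PrognosticRecord]:
    """Median-split log-rank screen; returns records for genes with p < alpha.

    Samples at or below the median go to the low-expression group. Direction is
    adverse when the high-expression group has more events per unit follow-up
    (worse survival).
    """
    expr = log_expression(expression)
    shared = [s for s in expr.columns if s in clinical.index]
    if len(shared) < 4:
        raise InvalidInputError("need >= 4 samples with clinical data")
    expr = expr[shared]
    times = clinical.loc[shared, "OS_time"].to_numpy(dtype=float)
    events = clinical.loc[shared, "OS_event"].to_numpy(dtype=int)
    if (times <= 0).any():
        raise InvalidInputError("OS_time must be > 0")
    if events.sum() == 0:
        warnings.warn("all samples censored; no genes can be screened")
        return []

    gene_list = [g for g in expr.index if genes is None or g in genes]
    out: list[PrognosticRecord] = []
    for g in gene_list:
        vals = expr.loc[g].to_numpy(dtype=float)
        med = np.median(vals)
        high = vals > med  # ties at the median go to the low group
        if high.sum() == 0 or (~high).sum() == 0:
            warnings.warn(f"gene {g}: constant expression, no valid split; skipped")
            continue
        stat, p, _ = logrank_test(times, events, high.astype(int))
        # event rate per unit follow-up as the direction heuristic
        rate_high = events[high].sum() / times[high].sum()
        rate_low = events[~high].sum() / times[~high].sum()
        direction = "adverse" if rate_high > rate_low else "favorable"
        if p < alpha:
            out.append(PrognosticRecord(g, stat, p, direction, "median split on log2(FPKM+1)"))
    return out


def intersect_gene_sets(a: set[str], b: set[str]) -> set[str]:
    return set(a) & set(b)
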