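"""Between-subtype contrasts: state tests, differential expression, mutations,
survival, score rank tests, marker tiers and over-representation analysis.

Exact contingency tests (2x2 and 2x3) are computed by full enumeration of the
conditional (multiple hypergeometric) distribution when the table total is
small, switching to a seeded Monte-Carlo approximation otherwise. Differential
expression is a negative-binomial Wald test on median-of-ratios normalized
counts with per-gene method-of-moments dispersion — a deliberately simple
stand-in for shrinkage-based NB machinery, keeping the published decision rule
(absolute log2 fold change >= 1 and BH FDR < 0.05).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test as _ll_multivariate

from ._stats import bh_adjust
from .errors import InvalidInputError
from .event_stats import EventThresholds
from .matrix import OmicsMatrix, SubtypeAssignment

CNV_STATES = ("Gain", "Loss", "Normal")
MET_STATES = ("HyperMethy", "HypoMethy", "Normal")


@dataclass(frozen=True)
class DifferentialResult:
    feature: str
    test: str
    effect: float
    p: float
    fdr: float = float("nan")


@dataclass
class MarkerStratification:
    gene: str
    tiers: dict[str, str]  # sample -> L1/L2/L3
    global_p: float
    pairwise_p: dict[str, float]
    direction: str


# ---------------------------------------------------------------------------
# state calling and exact tests
# ---------------------------------------------------------------------------

def call_states(
    matrix: OmicsMatrix, thresholds: EventThresholds = EventThresholds()
) -> pd.DataFrame:
    """Categorical state matrix from a CNV or beta matrix using event thresholds."""
    x = matrix.to_numpy()
    if matrix.kind == "cnv_logratio":
        out = np.where(x > thresholds.cnv_gain, "Gain",
                       np.where(x < thresholds.cnv_loss, "Loss", "Normal"))
    elif matrix.kind == "beta":
        out = np.where(x > thresholds.beta_hyper, "HyperMethy",
                       np.where(x < thresholds.beta_hypo, "HypoMethy", "Normal"))
    else:
        raise InvalidInputError("state calling needs a cnv_logratio or beta matrix")
    out = out.astype(object)
    out[~np.isfinite(x)] = None
    return pd.DataFrame(out, index=matrix.genes, columns=matrix.samples)


def _log_table_prob(first_row: np.ndarray, colsums: np.ndarray, r1: int, n_total: int) -> float:
    # multiple hypergeometric: prod C(c_j, a_j) / C(N, r1)
    a = first_row
    c = colsums
    num = gammaln(c + 1).sum() - gammaln(a + 1).sum() - gammaln(c - a + 1).sum()
    den = gammaln(n_total + 1) - gammaln(r1 + 1) - gammaln(n_total - r1 + 1)
    return float(num - den)


def exact_rx_c_p(table: np.ndarray, seed: int = 0, n_monte_carlo: int = 100_000,
                 enumeration_limit: int = 200) -> float:
    """Two-sided exact p for a 2xC table (probability-ordering rule).

    Full enumeration of all tables with the observed margins when the total is
    at most ``enumeration_limit``; otherwise a seeded Monte-Carlo estimate from
    the multiple hypergeometric null.
    """
    t = np.asarray(table, dtype=int)
    if t.shape[0] != 2:
        raise InvalidInputError("exact test implemented for two groups")
    colsums = t.sum(axis=0)
    keep = colsums > 0
    t = t[:, keep]
    colsums = colsums[keep]
    if t.shape[1] == 0 or t.sum() == 0:
        return 1.0
    r1 = int(t[0].sum())
    n_total = int(t.sum())
    obs_logp = _log_table_prob(t[0], colsums, r1, n_total)
    tol = 1e-9

    if n_total <= enumeration_limit:
        ncol = len(colsums)
        total = 0.0
        row = np.zeros(ncol, dtype=int)

        def rec(j: int, remaining: int) -> float:
            if j == ncol - 1:
                if 0 <= remaining <= colsums[j]:
                    row[j] = remaining
                    lp = _log_table_prob(row, colsums, r1, n_total)
                    return float(np.exp(lp)) if lp <= obs_logp + tol else 0.0
                return 0.0
            acc = 0.0
            lo = max(0, remaining - int(colsums[j + 1:].sum()))
            hi = min(int(colsums[j]), remaining)
            for a in range(lo, hi + 1):
                row[j] = a
                acc += rec(j + 1, remaining - a)
            return acc

        total = rec(0, r1)
        return min(1.0, total)

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(colsums, r1, size=n_monte_carlo)
    lp = (gammaln(colsums + 1).sum()
          - gammaln(draws + 1).sum(axis=1)
          - gammaln(colsums - draws + 1).sum(axis=1)
          - (gammaln(n_total + 1) - gammaln(r1 + 1) - gammaln(n_total - r1 + 1)))
    count = int((lp <= obs_logp + tol).sum())
    return (count + 1) / (n_monte_carlo + 1)


def fisher_state_test(
    states: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    state_order=None,
    seed: int = 0,
) -> list[DifferentialResult]:
    """Per-feature exact test of state distribution between two sample groups."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise InvalidInputError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise InvalidInputError("groups must be disjoint")
    cols = set(states.columns)
    missing = [s for s in group_a + group_b if s not in cols]
    if missing:
        raise InvalidInputError(f"samples absent from state matrix: {missing[:5]}")

    if state_order is None:
        observed = pd.unique(states[group_a + group_b].to_numpy().ravel())
        state_order = [s for s in (*CNV_STATES, *MET_STATES) if s in set(observed)]
    results = []
    for feature, row in states.iterrows():
        table = np.array([
            [int((row[group_a] == s).sum()) for s in state_order],
            [int((row[group_b] == s).sum()) for s in state_order],
        ])
        p = exact_rx_c_p(table, seed=seed)
        results.append(DifferentialResult(str(feature), "fisher_state", float("nan"), p))
    fdr = bh_adjust(np.array([r.p for r in results]))
    return [DifferentialResult(r.feature, r.test, r.effect, r.p, float(f))
            for r, f in zip(results, fdr)]


# ---------------------------------------------------------------------------
# negative-binomial differential expression
# ---------------------------------------------------------------------------

def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors: median of per-sample ratios to the geometric mean."""
    counts = np.asarray(counts, dtype=float)
    usable = np.all(counts > 0, axis=1)
    if not usable.any():
        raise InvalidInputError("no gene with all-positive counts; cannot derive size factors")
    logc = np.log(counts[usable])
    log_gm = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - log_gm, axis=0))


def nb_differential_expression(
    counts: OmicsMatrix,
    group_a: list[str],
    group_b: list[str],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """NB Wald test of group_b vs group_a on normalized counts.

    Returns a frame with log2FC (b over a), Wald p, BH fdr and the published
    significance rule |log2FC| >= lfc_threshold AND fdr < fdr_threshold.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise InvalidInputError("both groups need >= 2 samples")
    df = counts.values
    k = df[group_a + group_b].to_numpy(dtype=float)
    n_a = len(group_a)
    sf = median_of_ratios_size_factors(k)
    y = k / sf[None, :]

    nonzero = k.sum(axis=1) > 0
    skipped = (~nonzero).sum()
    if skipped:
        warnings.warn(f"{skipped} genes all-zero in both groups; skipped")
    genes = df.index[nonzero]
    y = y[nonzero]

    ya, yb = y[:, :n_a], y[:, n_a:]
    mean_a, mean_b = ya.mean(axis=1), yb.mean(axis=1)
    var_w = (((ya - mean_a[:, None]) ** 2).sum(axis=1)
             + ((yb - mean_b[:, None]) ** 2).sum(axis=1)) / max(y.shape[1] - 2, 1)
    mu_pool = (mean_a + mean_b) / 2.0
    inv_sf_mean = (1.0 / sf).mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = (var_w - mu_pool * inv_sf_mean) / (mu_pool ** 2)
    disp = np.nan_to_num(disp, nan=1e-8)
    disp = np.maximum(disp, 1e-8)

    inv_a = (1.0 / sf[:n_a]).mean()
    inv_b = (1.0 / sf[n_a:]).mean()
    var_mean_a = (mean_a * inv_a + disp * mean_a ** 2) / n_a
    var_mean_b = (mean_b * inv_b + disp * mean_b ** 2) / len(group_b)
    ln2 = np.log(2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2(mean_b / mean_a)
        se = np.sqrt(var_mean_a / (mean_a ** 2) + var_mean_b / (mean_b ** 2)) / ln2
        wald = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    bad = ~np.isfinite(wald)  # zero SE or infinite fold change
    p[bad] = np.where(np.abs(log2fc[bad]) > 0, 0.0, 1.0)
    fdr = bh_adjust(p)
    out = pd.DataFrame({
        "gene": genes,
        "base_mean": mu_pool,
        "log2fc": log2fc,
        "dispersion": disp,
        "p": p,
        "fdr": fdr,
    })
    out["significant"] = (np.abs(out["log2fc"]) >= lfc_threshold) & (out["fdr"] < fdr_threshold)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# mutations, survival, scores, enrichment
# ---------------------------------------------------------------------------

def mutation_frequency_test(
    mutations: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene 2x2 Fisher exact test of mutated-sample counts between groups."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise InvalidInputError("both groups must be non-empty")
    if len(mutations) == 0:
        return pd.DataFrame(columns=["gene", "mut_a", "mut_b", "odds_ratio", "p", "fdr",
                                     "significant"])
    sets = (
        mutations.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].agg(set)
    )
    rows = []
    sa, sb = set(group_a), set(group_b)
    for gene, carriers in sets.items():
        ma = len(carriers & sa)
        mb = len(carriers & sb)
        if ma == 0 and mb == 0:
            continue
        table = [[ma, len(group_a) - ma], [mb, len(group_b) - mb]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"gene": gene, "mut_a": ma, "mut_b": mb, "odds_ratio": odds, "p": p})
    if not rows:
        return pd.DataFrame(columns=["gene", "mut_a", "mut_b", "odds_ratio", "p", "fdr",
                                     "significant"])
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] < alpha  # the published rule thresholds the raw p
    return out


def km_logrank(
    clinical: pd.DataFrame,
    assignment: SubtypeAssignment,
) -> tuple[pd.DataFrame, float, pd.DataFrame, dict[int, pd.DataFrame]]:
    """KM tables per group plus global and pairwise log-rank tests.

    Returns (pairwise frame, global p, global summary frame, KM step tables).
    """
    shared = [s for s in assignment.samples if s in clinical.index]
    if len(shared) < 2:
        raise InvalidInputError("assignment and clinical table share too few samples")
    labels = assignment.label_array(shared)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups for survival comparison")
    times = clinical.loc[shared, "OS_time"].to_numpy(dtype=float)
    events = clinical.loc[shared, "OS_event"].to_numpy(dtype=int)

    km_tables: dict[int, pd.DataFrame] = {}
    for g in groups:
        mask = labels == g
        if events[mask].sum() == 0:
            warnings.warn(f"group {g} has zero events")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        tbl = kmf.survival_function_.reset_index()
        tbl.columns = ["time", "survival"]
        km_tables[g] = tbl

    glob = _ll_multivariate(times, labels, events)
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            m1, m2 = labels == g1, labels == g2
            res = _ll_logrank(times[m1], times[m2], events[m1], events[m2])
            rows.append({"group_1": g1, "group_2": g2,
                         "statistic": float(res.test_statistic),
                         "p": float(res.p_value),
                         "significant": bool(res.p_value < 0.05)})
    pairwise = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "statistic": [float(glob.test_statistic)],
        "p": [float(glob.p_value)],
        "df": [len(groups) - 1],
    })
    return pairwise, float(glob.p_value), summary, km_tables


def stratify_marker_expression(
    expression: OmicsMatrix,
    gene: str,
    clinical: pd.DataFrame,
    seed: int = 0,
) -> MarkerStratification:
    """Tertile (L1 low / L2 middle / L3 high) stratification with log-rank tests."""
    if gene not in expression.values.index:
        raise InvalidInputError(f"gene {gene} absent from expression matrix")
    shared = [s for s in expression.samples if s in clinical.index]
    if len(shared) < 6:
        raise InvalidInputError("need at least 6 samples for tertiles")
    vals = expression.values.loc[gene, shared].to_numpy(dtype=float)
    if np.unique(vals).size < 3:
        warnings.warn(f"gene {gene}: heavy ties; breaking with seeded jitter")
        vals = vals + np.random.default_rng(seed).normal(0, 1e-9, size=vals.size)
    order = np.argsort(vals, kind="stable")
    tiers = np.empty(len(shared), dtype=object)
    for name, chunk in zip(("L1", "L2", "L3"), np.array_split(order, 3)):
        tiers[chunk] = name

    times = clinical.loc[shared, "OS_time"].to_numpy(dtype=float)
    events = clinical.loc[shared, "OS_event"].to_numpy(dtype=int)
    glob = _ll_multivariate(times, tiers.astype(str), events)
    pairwise = {}
    for a, b in (("L1", "L2"), ("L2", "L3"), ("L1", "L3")):
        ma, mb = tiers == a, tiers == b
        res = _ll_logrank(times[ma], times[mb], events[ma], events[mb])
        pairwise[f"{a}~{b}"] = float(res.p_value)

    rates = {}
    for name in ("L1", "L2", "L3"):
        m = tiers == name
        rates[name] = events[m].sum() / times[m].sum() if times[m].sum() > 0 else np.nan
    direction = "adverse" if rates["L3"] > rates["L1"] else "favorable"
    return MarkerStratification(
        gene=gene,
        tiers={s: str(t) for s, t in zip(shared, tiers)},
        global_p=float(glob.p_value),
        pairwise_p=pairwise,
        direction=direction,
    )


def compare_scores_across_subtypes(
    scores: pd.Series,
    assignment: SubtypeAssignment,
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Kruskal-Wallis across groups + BH-adjusted pairwise rank-sum tests."""
    shared = [s for s in assignment.samples if s in scores.index]
    labels = assignment.label_array(shared)
    vals = scores.loc[shared].to_numpy(dtype=float)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2 or any((labels == g).sum() < 2 for g in groups):
        raise InvalidInputError("need >= 2 groups with >= 2 samples each")
    by_group = [vals[labels == g] for g in groups]
    if np.unique(vals).size == 1:
        warnings.warn("constant scores; rank test undefined, reporting p = 1")
        kw_p, kw_h = 1.0, 0.0
    else:
        kw_h, kw_p = stats.kruskal(*by_group)
    rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            a, b = vals[labels == g1], vals[labels == g2]
            if np.unique(np.concatenate([a, b])).size == 1:
                p = 1.0
            else:
                _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            rows.append({"group_1": g1, "group_2": g2, "p": float(p)})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["fdr"] = bh_adjust(pairwise["p"].to_numpy())
    medians = pd.DataFrame({
        "group": groups,
        "median": [float(np.median(vals[labels == g])) for g in groups],
        "n": [int((labels == g).sum()) for g in groups],
    })
    return pairwise, float(kw_p), medians


def hypergeometric_enrichment(
    hits: set[str],
    universe: set[str],
    collections: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``hits`` in each gene set."""
    if not universe:
        raise InvalidInputError("empty universe")
    hits = set(hits) & set(universe)
    m = len(universe)
    n_hits = len(hits)
    rows = []
    for term, members in collections.items():
        members = set(members) & set(universe)
        overlap = len(members & hits)
        if len(members) == 0:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, m, len(members), n_hits))
        rows.append({"term": term, "term_size": len(members), "overlap": overlap,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    else:
        out["fdr"] = []
    return out
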