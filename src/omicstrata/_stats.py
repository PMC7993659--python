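"""Shared statistical primitives.

Small, vectorized routines used by several stages: Benjamini-Hochberg
adjustment, Pearson correlation with the t-transform p-value, and a fast
log-rank test. The log-rank implementation here is deliberately independent of
lifelines (which backs the Kaplan-Meier reporting route) so the two can be
cross-checked.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import InvalidInputError


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment. NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r and two-sided p from the t transform with n-2 df.

    Pairs with a non-finite member are dropped. Returns (r, p, n_pairs);
    r is NaN when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return np.nan, np.nan, n
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def rowwise_pearson(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row Pearson r between matching rows of ``a`` and ``b`` (no NaNs).

    Returns (r, p) arrays; p from the t transform with n-2 df.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac * ac).sum(axis=1))
    sb = np.sqrt((bc * bc).sum(axis=1))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / denom
    r = np.clip(r, -1.0, 1.0)
    r[denom == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def fisher_z(r):
    """z = ln((1+r)/(1-r)); +/-inf at |r|=1."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.log((1.0 + r) / (1.0 - r))
    if z.ndim == 0:
        return float(z)
    return z


def logrank_test(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> tuple[float, float, int]:
    """Multi-group log-rank test.

    Parameters
    ----------
    times, events:
        Observed times (> 0) and event indicators in {0, 1}.
    groups:
        Integer or string labels; k distinct values give k-1 degrees of freedom.

    Returns
    -------
    (chi2, p, df)
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if times.size != events.size or times.size != groups.size:
        raise InvalidInputError("times, events and groups must have equal length")
    labels, gidx = np.unique(groups, return_inverse=True)
    k = labels.size
    if k < 2:
        raise InvalidInputError("log-rank test needs at least two groups")
    if events.sum() == 0:
        return 0.0, 1.0, k - 1

    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    g = gidx[order]

    event_times = np.unique(t[e == 1])
    # at-risk counts per group at each event time: n_j(t) = #(t_i >= t)
    # events per group at each event time
    nt = event_times.size
    n_at_risk = np.zeros((nt, k))
    d_events = np.zeros((nt, k))
    for j in range(k):
        tj = t[g == j]
        ej = t[(g == j) & (e == 1)]
        n_at_risk[:, j] = tj.size - np.searchsorted(tj, event_times, side="left")
        lo = np.searchsorted(ej, event_times, side="left")
        hi = np.searchsorted(ej, event_times, side="right")
        d_events[:, j] = hi - lo

    n_tot = n_at_risk.sum(axis=1)
    d_tot = d_events.sum(axis=1)
    valid = n_tot > 0
    n_at_risk, d_events = n_at_risk[valid], d_events[valid]
    n_tot, d_tot = n_tot[valid], d_tot[valid]

    frac = n_at_risk / n_tot[:, None]
    observed = d_events.sum(axis=0)
    expected = (d_tot[:, None] * frac).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        hyper = d_tot * (n_tot - d_tot) / np.where(n_tot > 1, n_tot - 1, 1.0)
    hyper[n_tot <= 1] = 0.0
    # covariance: V_jl = sum_t hyper_t * (delta_jl * f_j - f_j f_l)
    v = np.einsum("t,tj,tl->jl", -hyper, frac, frac)
    v[np.diag_indices(k)] += (hyper[:, None] * frac).sum(axis=0)

    diff = (observed - expected)[: k - 1]
    vsub = v[: k - 1, : k - 1]
    try:
        sol = np.linalg.solve(vsub, diff)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(vsub) @ diff
    chi2 = float(diff @ sol)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p, k - 1
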