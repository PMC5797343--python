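"""Nonparametric testing toolkit, implemented from the definitions.

All tests here are computed from rank/enumeration first principles rather
than delegated to scipy, because tie handling, exact-vs-approximate
switchovers and the post hoc critical-difference rule are part of the
analysis contract.  Average ranks are used for ties throughout; tests are
two-sided by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps  # distribution quantiles only

__all__ = [
    "TestResult",
    "rankdata",
    "mann_whitney",
    "kruskal_wallis",
    "posthoc_pairwise",
    "spearman",
    "kendall",
    "bh_adjust",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...] = ()
    adjusted_p: float | None = None
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def rankdata(x) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _mw_exact_counts(n1: int, n2: int) -> np.ndarray:
    """Number of group labelings yielding each U value (no ties).

    The null distribution of U is the coefficient sequence of the Gaussian
    binomial coefficient [n1+n2 choose n1]_q, computed exactly as the
    polynomial  prod_{j=1..n1} (1 - q^{n2+j}) / (1 - q^j).
    """
    max_u = n1 * n2
    c = np.zeros(max_u + 1, dtype=np.int64)
    c[0] = 1
    for j in range(1, n1 + 1):
        # multiply by (1 - q^{n2+j})
        m = n2 + j
        nxt = c.copy()
        nxt[m:] -= c[:-m] if m <= max_u else 0
        # divide by (1 - q^j): cumulative sum with stride j
        for u in range(j, max_u + 1):
            nxt[u] += nxt[u - j]
        c = nxt
    return c.astype(float)


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    Exact enumeration of the U null distribution when combined n <= 20 and
    there are no ties; otherwise normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    has_ties = len(np.unique(combined)) < n1 + n2

    if n1 + n2 <= 20 and not has_ties:
        counts = _mw_exact_counts(n1, n2)
        total = counts.sum()
        cdf = np.cumsum(counts) / total
        sf = np.cumsum(counts[::-1])[::-1] / total  # P(U >= u)
        u1i = int(round(u1))
        if alternative == "two-sided":
            p = 2.0 * min(cdf[u1i], sf[u1i])
        elif alternative == "greater":
            p = sf[u1i]
        else:
            p = cdf[u1i]
        p = min(p, 1.0)
        method = "mann-whitney-exact"
    else:
        n = n1 + n2
        mean_u = n1 * n2 / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u == 0:
            return TestResult(u1, 1.0, "mann-whitney-normal", (n1, n2))
        if alternative == "two-sided":
            z = (abs(u1 - mean_u) - 0.5) / math.sqrt(var_u)
            p = 2.0 * _sps.norm.sf(max(z, 0.0))
        elif alternative == "greater":
            z = (u1 - mean_u - 0.5) / math.sqrt(var_u)
            p = _sps.norm.sf(z)
        else:
            z = (u1 - mean_u + 0.5) / math.sqrt(var_u)
            p = _sps.norm.cdf(z)
        p = min(p, 1.0)
        method = "mann-whitney-normal"
    return TestResult(float(u1), float(p), method, (n1, n2))


# ---------------------------------------------------------------------------
# Kruskal-Wallis and kruskalmc-style post hoc


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    ns = [len(g) for g in groups]
    n = sum(ns)
    if n < 3:
        raise ValueError("need total n >= 3")
    combined = np.concatenate(groups)
    ranks = rankdata(combined)
    h = 0.0
    start = 0
    for gn in ns:
        r = ranks[start:start + gn]
        h += r.sum() ** 2 / gn
        start += gn
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(combined, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0.0:  # all values tied
        return TestResult(0.0, 1.0, "kruskal-wallis", tuple(ns))
    h /= correction
    p = float(_sps.chi2.sf(h, k - 1))
    return TestResult(float(h), p, "kruskal-wallis", tuple(ns))


def posthoc_pairwise(groups, alpha: float = 0.05, labels=None):
    """Pairwise multiple-comparison test after Kruskal-Wallis.

    Pair (i, j) is significant when the absolute difference of mean ranks
    (ranks over the pooled data) exceeds the critical difference

        z_{1 - alpha/(k(k-1))} * sqrt(N(N+1)/12 * (1/n_i + 1/n_j))

    Returns a list of dicts with observed and critical differences.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if labels is None:
        labels = [str(i) for i in range(k)]
    ns = [len(g) for g in groups]
    n = sum(ns)
    ranks = rankdata(np.concatenate(groups))
    mean_ranks = []
    start = 0
    for gn in ns:
        mean_ranks.append(ranks[start:start + gn].mean())
        start += gn
    z = float(_sps.norm.ppf(1.0 - alpha / (k * (k - 1))))
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            obs = abs(mean_ranks[i] - mean_ranks[j])
            crit = z * math.sqrt(n * (n + 1) / 12.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            out.append({
                "pair": (labels[i], labels[j]),
                "observed_difference": obs,
                "critical_difference": crit,
                "significant": bool(obs > crit),
            })
    return out


# ---------------------------------------------------------------------------
# rank correlations


def spearman(x, y) -> TestResult:
    """Spearman rho on average ranks; p from the t approximation (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or n != len(y):
        raise ValueError("need n >= 3 matched pairs")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return TestResult(float("nan"), float("nan"), "spearman", (n,),
                          undefined=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * _sps.t.sf(abs(t), n - 2))
    return TestResult(rho, p, "spearman", (n,))


def kendall(x, y) -> TestResult:
    """Kendall tau-b with tie correction; p by normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or n != len(y):
        raise ValueError("need n >= 3 matched pairs")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        return TestResult(float("nan"), float("nan"), "kendall-tau-b", (n,),
                          undefined=True)
    # pairwise concordance by direct O(n^2) comparison (n is small here)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, 1)
    prod = dx[iu] * dy[iu]
    conc = int((prod > 0).sum())
    disc = int((prod < 0).sum())
    _, cx = np.unique(x, return_counts=True)
    _, cy = np.unique(y, return_counts=True)
    n0 = n * (n - 1) / 2.0
    n1 = float((cx * (cx - 1) / 2.0).sum())
    n2 = float((cy * (cy - 1) / 2.0).sum())
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return TestResult(float("nan"), float("nan"), "kendall-tau-b", (n,),
                          undefined=True)
    tau = (conc - disc) / denom
    # tie-corrected variance of S = conc - disc (standard tau-b inference)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((cx * (cx - 1) * (2 * cx + 5)).sum())
    vu = float((cy * (cy - 1) * (2 * cy + 5)).sum())
    v1 = float((cx * (cx - 1)).sum()) * float((cy * (cy - 1)).sum()) / (
        2.0 * n * (n - 1))
    v2 = float((cx * (cx - 1) * (cx - 2)).sum()) * float(
        (cy * (cy - 1) * (cy - 2)).sum()) / (9.0 * n * (n - 1) * (n - 2))
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        p = 1.0
    else:
        z = (conc - disc) / math.sqrt(var_s)
        p = float(2.0 * _sps.norm.sf(abs(z)))
    return TestResult(float(tau), min(p, 1.0), "kendall-tau-b", (n,))


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    ok = ~np.isnan(p)
    adj = np.full(m, np.nan)
    pv = p[ok]
    k = pv.size
    if k:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * k / np.arange(1, k + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(k)
        out[order] = np.minimum(ranked, 1.0)
        adj[ok] = out
    return adj
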