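"""Compositionally-robust taxon-association network inference.

Counts are centered-log-ratio transformed, each taxon is regressed on all
others with an L1 penalty (neighborhood selection), and the penalty is
chosen by StARS: the sparsest lambda whose edge-selection instability over
random subsamples stays below a threshold.  Edges are symmetrized (OR rule
by default), weighted by the mean of the available directed coefficients,
and small-magnitude edges (< 0.05 by default) are dropped, mirroring the
display rule used for the study's networks.

Edge weights are penalized regression coefficients, not correlations, even
though association-network figures conventionally call them correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .data_io import CountTable, TaxonomyTable

__all__ = [
    "AssociationNetwork",
    "StarsSettings",
    "clr_transform",
    "lambda_max",
    "neighborhood_selection",
    "neighborhood_path",
    "stars_select",
    "build_network",
    "fit_network",
    "network_summaries",
]

logger = logging.getLogger(__name__)


@dataclass
class AssociationNetwork:
    """Signed weighted undirected taxon-association graph."""

    nodes: list[str]
    edges: dict[tuple[str, str], float]  # (a, b) with a < b -> signed weight
    lambda_selected: float | None = None
    n_subsamples: int | None = None

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValueError("self-edge")
            if a > b:
                raise ValueError("edge keys must be ordered (a < b)")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sign(self, pair) -> int:
        return int(np.sign(self.edges[pair]))

    def adjacency(self) -> np.ndarray:
        """Binarized symmetric 0/1 adjacency in node order."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        a = np.zeros((len(self.nodes), len(self.nodes)))
        for (u, v) in self.edges:
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
        return a

    def degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for (u, v) in self.edges:
            d[u] += 1
            d[v] += 1
        return d


@dataclass
class StarsSettings:
    n_lambda: int = 20
    min_lambda_ratio: float = 0.01
    n_subsamples: int = 50
    instability_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_lambda_ratio < 1.0:
            raise ValueError("min_lambda_ratio must be in (0, 1)")
        if self.n_subsamples < 2:
            raise ValueError("n_subsamples must be >= 2")
        if self.n_lambda < 2:
            raise ValueError("lambda path needs >= 2 points")


def clr_transform(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform: per sample, log(count + pseudocount)
    minus the mean of those logs.  Returns samples x taxa; rows sum to 0."""
    if isinstance(counts, CountTable):
        mat = counts.counts.T.astype(float)
    else:
        mat = np.asarray(counts, dtype=float)
    if mat.min() < 0:
        raise ValueError("counts must be non-negative")
    logs = np.log(mat + pseudocount)
    return logs - logs.mean(axis=1, keepdims=True)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def lambda_max(clr_matrix: np.ndarray) -> float:
    """Smallest penalty at which every neighborhood is empty: the maximum
    absolute off-diagonal entry of the standardized column covariance."""
    x = _standardize(np.asarray(clr_matrix, dtype=float))
    n = x.shape[0]
    g = x.T @ x / n
    np.fill_diagonal(g, 0.0)
    return float(np.abs(g).max())


@njit(cache=False)
def _cd_advance(gram: np.ndarray, lam: float, betas: np.ndarray,
                residuals: np.ndarray, tol: float, max_sweeps: int) -> None:
    """Advance the per-target coordinate-descent state to penalty ``lam``.

    ``gram`` is X'X / n for standardized X (unit diagonal), so the update
    for coordinate k of target j is a soft-threshold of the partial
    residual correlation.  ``betas[j]`` and ``residuals[j]`` hold the
    warm-start solution and X'(x_j - X b)/n for target j; both are updated
    in place, solving min 1/(2n)||x_j - X b||^2 + lam |b|_1 per target.
    """
    p = gram.shape[0]
    for j in range(p):
        beta = betas[j]
        resid = residuals[j]
        for _sweep in range(max_sweeps):
            max_delta = 0.0
            for k in range(p):
                if k == j:
                    continue
                z = resid[k] + beta[k]
                if z > lam:
                    nb = z - lam
                elif z < -lam:
                    nb = z + lam
                else:
                    nb = 0.0
                d = nb - beta[k]
                if d != 0.0:
                    for m in range(p):
                        resid[m] -= gram[m, k] * d
                    beta[k] = nb
                    if abs(d) > max_delta:
                        max_delta = abs(d)
            if max_delta < tol:
                break


def _cd_lasso_path(gram: np.ndarray, lambdas: np.ndarray, tol: float,
                   max_sweeps: int) -> np.ndarray:
    """Coefficients for every target at every lambda of a descending path,
    warm-started; shape (n_lambda, p, p)."""
    p = gram.shape[0]
    betas = np.zeros((p, p))
    residuals = np.ascontiguousarray(gram.T).copy()  # row j = gram[:, j]
    out = np.zeros((len(lambdas), p, p))
    for li, lam in enumerate(lambdas):
        _cd_advance(gram, float(lam), betas, residuals, tol, max_sweeps)
        out[li] = betas
    return out


def neighborhood_selection(clr_matrix: np.ndarray, lam: float) -> np.ndarray:
    """L1-penalized regression of each (standardized) taxon column on all
    others at penalty ``lam`` (coordinate descent, tolerance 1e-6, at most
    1000 sweeps).

    Returns the directed coefficient matrix B with B[j, k] the coefficient
    of predictor k in the regression for target j (diagonal zero).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0 (unpenalized fits are unstable)")
    x = _standardize(np.asarray(clr_matrix, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in CLR matrix")
    n, p = x.shape
    if n < 10:
        logger.warning("neighborhood selection with only %d samples", n)
    return neighborhood_path(x, np.array([float(lam)]))[0]


def neighborhood_path(x_std: np.ndarray, lambdas: np.ndarray,
                      tol: float = 1e-6, max_sweeps: int = 1000) -> np.ndarray:
    """Directed coefficients at every lambda of a descending path, per
    target node; shape (n_lambda, p, p)."""
    x = np.ascontiguousarray(x_std, dtype=float)
    n = x.shape[0]
    gram = x.T @ x / n
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda path must be non-increasing")
    return _cd_lasso_path(gram, lambdas, tol, max_sweeps)


def _edge_support(coefs: np.ndarray, rule: str = "OR") -> np.ndarray:
    sel = coefs != 0
    return (sel | sel.T) if rule == "OR" else (sel & sel.T)


def stars_select(clr_matrix: np.ndarray, settings: StarsSettings):
    """StARS penalty selection.

    Lambda path: ``n_lambda`` log-spaced values from lambda_max (taken over
    the full data and every subsample, so the path starts at the empty
    model everywhere) down to lambda_max * min_lambda_ratio.  For each
    lambda, neighborhoods are fit on
    ``n_subsamples`` random subsamples of size floor(10*sqrt(n)) capped at
    n - 1; per-edge (OR-symmetrized) selection frequencies f give the total
    instability D(lambda) = mean of 2 f (1 - f) over all possible edges.
    The selected lambda* is the smallest (densest) lambda whose running
    supremum of D from lambda_max down remains <= the threshold; the path
    walk stops at the first crossing, which cannot change the selection.

    Returns ``(lambda_star, stability, lambdas, instabilities)`` where
    ``stability`` is the p x p edge selection-frequency matrix at lambda*
    and the last two entries cover the visited part of the path.
    """
    x = _standardize(np.asarray(clr_matrix, dtype=float))
    n, p = x.shape
    lmax = lambda_max(x)
    b = min(int(np.floor(10.0 * np.sqrt(n))), n - 1)
    rng = np.random.default_rng(settings.seed)
    # draw all subsamples up front; duplicates (common when b = n - 1: only
    # n distinct leave-one-out sets exist) share one warm-started CD state
    keys = [tuple(sorted(rng.choice(n, size=b, replace=False)))
            for _ in range(settings.n_subsamples)]
    states: dict[tuple, tuple] = {}
    for key in keys:
        if key not in states:
            sub = _standardize(x[list(key)])
            gram = sub.T @ sub / sub.shape[0]
            states[key] = (gram, np.zeros((p, p)),
                           np.ascontiguousarray(gram.T).copy())
    # anchor the path top at the largest subsample lambda_max so the first
    # grid point selects nothing anywhere and D(lambda_max) = 0 exactly
    offdiag_max = max(
        float(np.abs(g - np.diag(np.diag(g))).max())
        for g, _, _ in states.values())
    lmax = max(lmax, offdiag_max)
    lambdas = np.logspace(np.log10(lmax),
                          np.log10(lmax * settings.min_lambda_ratio),
                          settings.n_lambda)
    iu = np.triu_indices(p, 1)
    n_pairs = len(iu[0])
    instab = []
    freqs = []
    # walk the path from lambda_max down; the running supremum of D is
    # monotone once it crosses the threshold, so the walk stops at the
    # first crossing — smaller lambdas cannot be selected
    for lam in lambdas:
        freq = np.zeros((p, p))
        # support estimation tolerates a looser CD tol than the final refit
        for gram, betas, residuals in states.values():
            _cd_advance(gram, float(lam), betas, residuals, 1e-5, 1000)
        for key in keys:
            freq += _edge_support(states[key][1])
        freq /= settings.n_subsamples
        freqs.append(freq)
        d = (2.0 * freq[iu] * (1.0 - freq[iu])).sum() / n_pairs
        instab.append(d)
        if d > settings.instability_threshold:
            break
    instab = np.asarray(instab)
    sup = np.maximum.accumulate(instab)
    ok = sup <= settings.instability_threshold
    li_star = int(np.max(np.flatnonzero(ok))) if ok.any() else 0
    return (float(lambdas[li_star]), freqs[li_star], lambdas[:len(instab)],
            instab)


def build_network(coefficients: np.ndarray, taxa: list[str],
                  symmetrization: str = "OR",
                  edge_threshold: float = 0.05,
                  lambda_selected: float | None = None,
                  n_subsamples: int | None = None) -> AssociationNetwork:
    """Symmetrize directed coefficients into a signed undirected network.

    OR rule: an edge exists if either direction selected it; weight is the
    mean of the available directed coefficients.  When the two directions
    disagree in sign, the larger-magnitude direction wins (logged).  Edges
    with |weight| < ``edge_threshold`` are dropped.
    """
    coefs = np.asarray(coefficients, dtype=float)
    p = len(taxa)
    edges: dict[tuple[str, str], float] = {}
    for i in range(p):
        for j in range(i + 1, p):
            cij, cji = coefs[i, j], coefs[j, i]
            if symmetrization == "OR":
                present = (cij != 0) or (cji != 0)
            else:
                present = (cij != 0) and (cji != 0)
            if not present:
                continue
            if cij != 0 and cji != 0 and np.sign(cij) != np.sign(cji):
                w = cij if abs(cij) >= abs(cji) else cji
                logger.warning("sign conflict on edge (%s, %s); keeping the "
                               "larger-magnitude direction", taxa[i], taxa[j])
            else:
                vals = [c for c in (cij, cji) if c != 0]
                w = float(np.mean(vals))
            if abs(w) < edge_threshold:
                continue
            edges[(min(taxa[i], taxa[j]), max(taxa[i], taxa[j]))] = float(w)
    return AssociationNetwork(list(taxa), edges, lambda_selected, n_subsamples)


def fit_network(counts, taxa: list[str] | None = None,
                settings: StarsSettings | None = None,
                symmetrization: str = "OR",
                edge_threshold: float = 0.05,
                pseudocount: float = 1.0) -> AssociationNetwork:
    """CLR -> StARS -> refit at lambda* on the full data -> signed network."""
    if settings is None:
        settings = StarsSettings()
    if isinstance(counts, CountTable):
        taxa = list(counts.taxa)
        clr = clr_transform(counts, pseudocount)
    else:
        clr = clr_transform(counts, pseudocount)
        if taxa is None:
            taxa = [f"v{i}" for i in range(clr.shape[1])]
    lam_star, _stab, _lams, _inst = stars_select(clr, settings)
    coefs = neighborhood_selection(clr, lam_star)
    return build_network(coefs, taxa, symmetrization, edge_threshold,
                         lambda_selected=lam_star,
                         n_subsamples=settings.n_subsamples)


def network_summaries(network: AssociationNetwork,
                      taxonomy: TaxonomyTable | None = None,
                      top_k: int = 5) -> dict:
    """Positive-edge fraction, hub nodes and within/between-genus sign counts."""
    n_pos = sum(1 for w in network.edges.values() if w > 0)
    n_neg = network.n_edges - n_pos
    degree = network.degree()
    strength = {n: 0.0 for n in network.nodes}
    for (u, v), w in network.edges.items():
        strength[u] += abs(w)
        strength[v] += abs(w)
    hubs = sorted(network.nodes,
                  key=lambda n: (-degree[n], -strength[n], n))[:top_k]
    summary = {
        "n_nodes": len(network.nodes),
        "n_edges": network.n_edges,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "positive_fraction": (n_pos / network.n_edges if network.n_edges
                              else 0.0),
        "hubs": hubs,
    }
    if taxonomy is not None:
        genus = dict(zip(network.nodes, taxonomy.genus_of(network.nodes)))
        counts = {"within_genus": {"positive": 0, "negative": 0},
                  "between_genus": {"positive": 0, "negative": 0}}
        for (u, v), w in network.edges.items():
            scope = "within_genus" if genus[u] == genus[v] else "between_genus"
            counts[scope]["positive" if w > 0 else "negative"] += 1
        summary["genus_edge_counts"] = counts
    return summary
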