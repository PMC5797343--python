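"""Weighted UniFrac and the distance-based analyses built on it.

UniFrac is computed through a branch x taxon incidence matrix: for each
branch, the abundance mass of the tips below it.  The raw weighted UniFrac
between samples A and B is  sum_branches  len_b * |P_A(b) - P_B(b)|; the
normalized variant divides by  sum_tips depth_j * (p_A(j) + p_B(j)), where
depth_j is the root-to-tip path length.  Distances over many samples share
one incidence matrix, which makes replicate simulations cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_io import CountTable, DistanceMatrix, SampleMetadata
from .preprocess import RelAbundanceTable, to_relative_abundance
from .stats_core import (TestResult, bh_adjust, kendall, kruskal_wallis,
                         posthoc_pairwise, rankdata, spearman)

__all__ = [
    "branch_matrix",
    "weighted_unifrac",
    "permanova",
    "anosim",
    "time_decay",
    "cross_site_temporal_correlation",
    "relation_distance_summary",
    "correlate_with_occupancy",
    "GroupedDistances",
]


# ---------------------------------------------------------------------------
# weighted UniFrac


def branch_matrix(tree: TreeNode, taxa: list[str]):
    """(incidence, lengths, depths): incidence is (n_branches x n_taxa) 0/1,
    row b marking the tips below branch b; lengths the branch lengths;
    depths the root-to-tip distance per taxon."""
    tip_index = {t: i for i, t in enumerate(taxa)}
    rows, lengths = [], []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        mask = np.zeros(len(taxa), dtype=float)
        if node.is_tip():
            # tree tips may be a superset of table taxa; extra tips carry
            # zero mass and their branches contribute nothing
            if node.name in tip_index:
                mask[tip_index[node.name]] = 1.0
        else:
            for child in node.children:
                mask += below[id(child)]
        below[id(node)] = mask
        if not node.is_root():
            rows.append(mask)
            lengths.append(float(node.length or 0.0))
    incidence = np.array(rows) if rows else np.zeros((0, len(taxa)))
    lengths = np.asarray(lengths, dtype=float)
    depths = lengths @ incidence  # root-to-tip distance per taxon
    return incidence, lengths, depths


def weighted_unifrac(table, tree: TreeNode,
                     normalized: bool = False) -> DistanceMatrix:
    """Pairwise weighted UniFrac between all samples of a table.

    ``table`` is a :class:`CountTable` (normalized internally) or a
    :class:`RelAbundanceTable`.  Raw (non-normalized) by default.
    """
    if isinstance(table, CountTable):
        table = to_relative_abundance(table)
    tips = {t.name for t in tree.tips()}
    present = np.asarray(table.fractions).sum(axis=1) > 0
    missing = [t for t, pr in zip(table.taxa, present) if pr and t not in tips]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:5]}")
    incidence, lengths, depths = branch_matrix(tree, table.taxa)
    p = incidence @ table.fractions  # branches x samples
    n = len(table.samples)
    d = np.zeros((n, n))
    w = lengths[:, None] if lengths.size else np.zeros((0, 1))
    for i in range(n):
        diff = np.abs(p[:, i:i + 1] - p[:, i + 1:])
        d[i, i + 1:] = (w * diff).sum(axis=0) if diff.size else 0.0
    if normalized:
        tipmass = depths @ table.fractions  # per-sample sum depth_j * p_j
        denom = tipmass[:, None] + tipmass[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, d / denom, 0.0)
        d = np.triu(d, 1)
    d = d + d.T
    return DistanceMatrix(list(table.samples), d)


# ---------------------------------------------------------------------------
# PERMANOVA / ANOSIM


def _group_indices(ids, grouping):
    if isinstance(grouping, dict):
        labels = [grouping[s] for s in ids]
    else:
        labels = list(grouping)
        if len(labels) != len(ids):
            raise ValueError("grouping length does not match ids")
    uniq = list(dict.fromkeys(labels))
    codes = np.array([uniq.index(g) for g in labels])
    return codes, uniq


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)  # sum over unordered pairs / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    df_between = k - 1
    df_within = n - k
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 999,
              seed: int = 0) -> TestResult:
    """One-way PERMANOVA: pseudo-F from the squared-distance partition,
    permutation p-value with the observed statistic included
    (p = (1 + #{F_perm >= F_obs}) / (1 + n_perm))."""
    codes, uniq = _group_indices(dm.ids, grouping)
    k = len(uniq)
    if k < 2:
        raise ValueError("need >= 2 groups")
    for g in range(k):
        if (codes == g).sum() < 2:
            raise ValueError(f"group {uniq[g]!r} has fewer than 2 samples")
    d2 = dm.data**2
    f_obs = _pseudo_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, k) >= f_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return TestResult(float(f_obs), float(p), "permanova",
                      tuple(int((codes == g).sum()) for g in range(k)))


def anosim(dm: DistanceMatrix, grouping, n_perm: int = 999,
           seed: int = 0) -> TestResult:
    """ANOSIM R = (mean between-group rank - mean within-group rank) / (M/2),
    ranking all unordered pairwise distances; permutation p as in permanova."""
    codes, uniq = _group_indices(dm.ids, grouping)
    k = len(uniq)
    if k < 2:
        raise ValueError("need >= 2 groups")
    for g in range(k):
        if (codes == g).sum() < 2:
            raise ValueError(f"group {uniq[g]!r} has fewer than 2 samples")
    n = len(codes)
    iu = np.triu_indices(n, 1)
    ranks = rankdata(dm.data[iu])
    m = len(ranks)

    def r_stat(c):
        within = c[iu[0]] == c[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = r_stat(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(codes)) >= r_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return TestResult(float(r_obs), float(p), "anosim",
                      tuple(int((codes == g).sum()) for g in range(k)))


# ---------------------------------------------------------------------------
# temporal / household analyses


def _within_cell_pairs(meta: pd.DataFrame):
    """Yield (individual, site, sample_a, sample_b, lag) for all same-site
    within-individual season pairs."""
    for (ind, site), sub in meta.groupby(["individual", "site"], sort=False):
        by_season = dict(zip(sub["season"], sub.index))
        seasons = sorted(by_season)
        for t1, t2 in itertools.combinations(seasons, 2):
            yield ind, site, by_season[t1], by_season[t2], abs(t2 - t1)


def time_decay(dm: DistanceMatrix, metadata: SampleMetadata) -> pd.DataFrame:
    """Per (individual, site): Spearman correlation between community
    similarity (1 - distance) and season lag.  Negative rho = time decay.
    Cells with fewer than 3 season pairs are skipped (flagged).  BH-adjusted
    across cells."""
    meta = metadata.for_samples(dm.ids)
    rows = []
    cells: dict[tuple, list] = {}
    for ind, site, a, b, lag in _within_cell_pairs(meta):
        cells.setdefault((ind, site), []).append((lag, 1.0 - dm.between(a, b)))
    for (ind, site), pairs in cells.items():
        if len(pairs) < 3:
            rows.append((ind, site, len(pairs), np.nan, np.nan, True))
            continue
        lags, sims = zip(*pairs)
        res = spearman(lags, sims)
        rows.append((ind, site, len(pairs), res.statistic, res.p_value,
                     res.undefined))
    df = pd.DataFrame(rows, columns=["individual", "site", "n_pairs", "rho",
                                     "p", "skipped"])
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
    return df


def cross_site_temporal_correlation(dm: DistanceMatrix,
                                    metadata: SampleMetadata):
    """Site x site Spearman correlations of within-individual temporal
    distances, matched on (individual, season pair).

    Returns ``(rho_frame, p_frame, p_adjusted_frame)``; only the upper
    triangle is filled (the matrix is symmetric by construction).
    """
    meta = metadata.for_samples(dm.ids)
    sites = list(dict.fromkeys(meta["site"]))
    per_site: dict[str, dict[tuple, float]] = {s: {} for s in sites}
    for ind, site, a, b, _lag in _within_cell_pairs(meta):
        sa = meta.loc[a, "season"]
        sb = meta.loc[b, "season"]
        per_site[site][(ind, min(sa, sb), max(sa, sb))] = dm.between(a, b)
    rho = pd.DataFrame(np.nan, index=sites, columns=sites)
    pval = pd.DataFrame(np.nan, index=sites, columns=sites)
    raw = []
    pairs = []
    for i, s1 in enumerate(sites):
        for s2 in sites[i + 1:]:
            keys = sorted(set(per_site[s1]) & set(per_site[s2]))
            if len(keys) < 3:
                continue
            x = [per_site[s1][k] for k in keys]
            y = [per_site[s2][k] for k in keys]
            res = spearman(x, y)
            rho.loc[s1, s2] = res.statistic
            pval.loc[s1, s2] = res.p_value
            raw.append(res.p_value)
            pairs.append((s1, s2))
    padj = pd.DataFrame(np.nan, index=sites, columns=sites)
    if raw:
        for (s1, s2), ap in zip(pairs, bh_adjust(raw)):
            padj.loc[s1, s2] = ap
    return rho, pval, padj


@dataclass
class GroupedDistances:
    """Pairwise distances labelled by household relation and season relation."""

    frame: pd.DataFrame  # columns: sample_a, sample_b, distance, relation,
    #          season_relation, season_a, season_b, household_a, household_b

    RELATIONS = ("same_individual", "cohabitant", "non_cohabitant")

    def values_for(self, relation: str,
                   season_relation: str | None = None) -> np.ndarray:
        sub = self.frame[self.frame["relation"] == relation]
        if season_relation is not None:
            sub = sub[sub["season_relation"] == season_relation]
        return sub["distance"].to_numpy()

    def quantiles(self, qs=(0.1, 0.25, 0.5, 0.75, 0.9)) -> pd.DataFrame:
        recs = {}
        for rel in self.RELATIONS:
            v = self.values_for(rel)
            recs[rel] = (np.quantile(v, qs) if v.size
                         else np.full(len(qs), np.nan))
        return pd.DataFrame(recs, index=[f"q{int(q * 100)}" for q in qs]).T


def relation_distance_summary(dm: DistanceMatrix, metadata: SampleMetadata):
    """Partition all pairwise distances into same-individual / cohabitant /
    non-cohabitant classes and test them.

    Returns ``(GroupedDistances, kw_result, posthoc_list)``.  Single-occupant
    households simply contribute no cohabitant pairs.
    """
    meta = metadata.for_samples(dm.ids)
    ind = meta["individual"].to_numpy()
    house = meta["household"].to_numpy()
    season = meta["season"].to_numpy()
    n = len(dm.ids)
    iu, ju = np.triu_indices(n, 1)
    same_ind = ind[iu] == ind[ju]
    same_house = house[iu] == house[ju]
    relation = np.where(same_ind, "same_individual",
                        np.where(same_house, "cohabitant", "non_cohabitant"))
    season_rel = np.where(season[iu] == season[ju], "same_season",
                          "different_season")
    frame = pd.DataFrame({
        "sample_a": np.asarray(dm.ids)[iu],
        "sample_b": np.asarray(dm.ids)[ju],
        "distance": dm.data[iu, ju],
        "relation": relation,
        "season_relation": season_rel,
        "season_a": season[iu],
        "season_b": season[ju],
        "household_a": house[iu],
        "household_b": house[ju],
    })
    grouped = GroupedDistances(frame)
    groups, labels = [], []
    for rel in GroupedDistances.RELATIONS:
        v = grouped.values_for(rel)
        if v.size:
            groups.append(v)
            labels.append(rel)
    kw = kruskal_wallis(groups) if len(groups) >= 2 else None
    post = posthoc_pairwise(groups, labels=labels) if len(groups) >= 2 else []
    return grouped, kw, post


def correlate_with_occupancy(per_individual_values: pd.DataFrame,
                             metadata: SampleMetadata) -> pd.DataFrame:
    """Kendall tau between a per-(individual, site) statistic and household
    occupancy; BH-adjusted across value columns.

    ``per_individual_values`` must carry 'individual' plus one or more value
    columns (optionally 'site'; tau is computed per value column over all
    rows, pooling sites the way the per-cell statistics are reported).
    """
    households = metadata.households
    occupancies = metadata.occupancies
    occ = np.array([occupancies[households[i]]
                    for i in per_individual_values["individual"]], dtype=float)
    value_cols = [c for c in per_individual_values.columns
                  if c not in ("individual", "site")]
    rows = []
    for col in value_cols:
        vals = per_individual_values[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if len(np.unique(occ[ok])) < 2 or ok.sum() < 3:
            rows.append((col, int(ok.sum()), np.nan, np.nan, True))
            continue
        res = kendall(occ[ok], vals[ok])
        rows.append((col, int(ok.sum()), res.statistic, res.p_value,
                     res.undefined))
    df = pd.DataFrame(rows, columns=["metric", "n", "tau", "p", "undefined"])
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
    return df
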