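"""Bayesian source tracking: mixing proportions of a sink community over
candidate source communities plus an Unknown source.

Collapsed Gibbs sampling over per-read source assignments.  A read of
taxon t is assigned to source v with probability proportional to

    (m_tv + n_tv + alpha1 * D) / (m_.v + n_.v + alpha1 * D * T) * (n_v + beta)

where m are the source's observed taxon counts, n the sink reads currently
assigned to v (excluding the read being updated), D the rarefaction depth
and T the number of taxa.  The Unknown source has no observed counts; its
taxon distribution is learned from the reads assigned to it under a
symmetric Dirichlet prior with per-taxon concentration alpha2 (unscaled:
a sharp unknown that can claim taxa no source explains).  Proportions are posterior
means of assignment fractions over draws and restarts.

Hyperparameter defaults (alpha1 0.001, alpha2 0.1, beta 10, burn-in 100,
10 draws, 10 restarts, rarefaction depth 1000) follow the published
defaults of the Bayesian source-tracking method this implements.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .data_io import CountTable, SampleMetadata
from .preprocess import filter_taxa
from .stats_core import TestResult, kendall

__all__ = [
    "SourceEstimate",
    "SamplerSettings",
    "gibbs_source_proportions",
    "run_seasonal_design",
    "cohabitant_aggregation",
]

UNKNOWN = "Unknown"


@dataclass
class SamplerSettings:
    alpha1: float = 0.001
    alpha2: float = 0.1
    beta: float = 10.0
    burnin: int = 100
    draws: int = 10
    restarts: int = 10
    rarefaction_depth: int = 1000


@dataclass
class SourceEstimate:
    sink: str
    sources: list[str]  # named sources, Unknown last
    proportions: np.ndarray  # aligned with sources; sums to 1
    posterior_sd: np.ndarray
    settings: SamplerSettings
    seed: int

    def __post_init__(self) -> None:
        if abs(float(self.proportions.sum()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if (self.proportions < -1e-12).any():
            raise ValueError("proportions must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.sources, map(float, self.proportions)))


@njit(cache=False)
def _gibbs_chain(read_taxa, m, msum, alpha1, alpha2, beta, depth,
                 burnin, draws, uniforms, init_uniforms):
    """One restart of the collapsed Gibbs chain; returns the (draws, V+1)
    matrix of assignment fractions recorded after each post-burn-in sweep."""
    n_reads = read_taxa.shape[0]
    n_named = m.shape[0]
    n_env = n_named + 1
    n_taxa = m.shape[1]
    nvt = np.zeros((n_env, n_taxa))
    nv = np.zeros(n_env)
    z = np.empty(n_reads, dtype=np.int64)
    for i in range(n_reads):
        v = int(init_uniforms[i] * n_env)
        if v >= n_env:
            v = n_env - 1
        z[i] = v
        nvt[v, read_taxa[i]] += 1.0
        nv[v] += 1.0
    prob = np.empty(n_env)
    out = np.zeros((draws, n_env))
    u_idx = 0
    for sweep in range(burnin + draws):
        for i in range(n_reads):
            t = read_taxa[i]
            v_old = z[i]
            nvt[v_old, t] -= 1.0
            nv[v_old] -= 1.0
            total = 0.0
            for v in range(n_named):
                pr = (m[v, t] + nvt[v, t] + alpha1 * depth) / \
                     (msum[v] + nv[v] + alpha1 * depth * n_taxa) * \
                     (nv[v] + beta)
                prob[v] = pr
                total += pr
            pr = (nvt[n_named, t] + alpha2) / \
                 (nv[n_named] + alpha2 * n_taxa) * \
                 (nv[n_named] + beta)
            prob[n_named] = pr
            total += pr
            r = uniforms[u_idx] * total
            u_idx += 1
            acc = 0.0
            v_new = n_env - 1
            for v in range(n_env):
                acc += prob[v]
                if r < acc:
                    v_new = v
                    break
            z[i] = v_new
            nvt[v_new, t] += 1.0
            nv[v_new] += 1.0
        if sweep >= burnin:
            for v in range(n_env):
                out[sweep - burnin, v] = nv[v] / n_reads
    return out


def _rarefy(vec: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    total = int(vec.sum())
    if total <= depth:
        return vec.astype(np.int64)
    reads = np.repeat(np.arange(len(vec)), vec.astype(np.int64))
    picked = rng.choice(reads, size=depth, replace=False)
    return np.bincount(picked, minlength=len(vec)).astype(np.int64)


def gibbs_source_proportions(sink, sources, source_names=None,
                             settings: SamplerSettings | None = None,
                             seed: int = 0) -> SourceEstimate:
    """Estimate mixing proportions of ``sink`` over ``sources`` + Unknown.

    ``sink`` is a taxon count vector; ``sources`` a list of count vectors on
    the same taxon axis.  Sink and sources larger than the rarefaction
    depth are subsampled without replacement.  Deterministic given seed.
    """
    if settings is None:
        settings = SamplerSettings()
    sink = np.asarray(sink, dtype=np.int64)
    if sink.sum() == 0:
        raise ValueError("empty sink")
    if len(sources) == 0:
        raise ValueError("need at least one source")
    sources = [np.asarray(s, dtype=np.int64) for s in sources]
    for s in sources:
        if s.shape != sink.shape:
            raise ValueError("sink and sources must share the taxon axis")
    if source_names is None:
        source_names = [f"source_{k}" for k in range(len(sources))]
    rng = np.random.default_rng(seed)
    depth = settings.rarefaction_depth
    sink_r = _rarefy(sink, depth, rng)
    m = np.array([_rarefy(s, depth, rng) for s in sources], dtype=float)
    msum = m.sum(axis=1)
    read_taxa = np.repeat(np.arange(len(sink_r)), sink_r)
    n_reads = len(read_taxa)
    n_env = len(sources) + 1
    all_draws = []
    for _ in range(settings.restarts):
        init_u = rng.random(n_reads)
        sweeps_u = rng.random((settings.burnin + settings.draws) * n_reads)
        chain = _gibbs_chain(read_taxa, m, msum, settings.alpha1,
                             settings.alpha2, settings.beta, float(depth),
                             settings.burnin, settings.draws, sweeps_u, init_u)
        all_draws.append(chain)
    stacked = np.vstack(all_draws)  # (restarts*draws, V+1)
    props = stacked.mean(axis=0)
    props = props / props.sum()
    sds = stacked.std(axis=0, ddof=1) if stacked.shape[0] > 1 else \
        np.zeros(n_env)
    return SourceEstimate(sink="sink", sources=list(source_names) + [UNKNOWN],
                          proportions=props, posterior_sd=sds,
                          settings=settings, seed=seed)


def run_seasonal_design(counts: CountTable, metadata: SampleMetadata,
                        min_prevalence: float = 0.10,
                        settings: SamplerSettings | None = None,
                        seed: int = 0,
                        individuals: list[str] | None = None,
                        seasons: list[int] | None = None) -> list[SourceEstimate]:
    """Per-season sink/source design.

    Taxa present in less than ``min_prevalence`` of all samples are excluded
    first.  Then, per season, each individual's samples are sinks and every
    other individual (five site samples pooled) is one named source
    environment.  Returns one :class:`SourceEstimate` per sink sample, with
    sink ids recorded.
    """
    filtered = filter_taxa(counts, 0, min_prevalence)
    meta = metadata.for_samples(filtered.samples)
    frame = filtered.to_frame()
    out = []
    season_values = seasons if seasons is not None else \
        sorted(meta["season"].unique())
    for season in season_values:
        season_meta = meta[meta["season"] == season]
        inds = list(dict.fromkeys(season_meta["individual"]))
        if len(inds) < 2:
            raise ValueError(f"season {season} has a single individual")
        pooled = {
            i: frame[season_meta.index[season_meta["individual"] == i]]
            .sum(axis=1).to_numpy()
            for i in inds
        }
        sink_inds = individuals if individuals is not None else inds
        for ind in sink_inds:
            source_names = [i for i in inds if i != ind]
            sources = [pooled[i] for i in source_names]
            for sid in season_meta.index[season_meta["individual"] == ind]:
                est = gibbs_source_proportions(
                    frame[sid].to_numpy(), sources, source_names,
                    settings=settings,
                    seed=int((seed * 1_000_003
                              + zlib.crc32(sid.encode()) % 65_536) % 2**31),
                )
                est.sink = sid
                out.append(est)
    return out


def cohabitant_aggregation(estimates: list[SourceEstimate],
                           metadata: SampleMetadata):
    """Aggregate named-source proportions by household relation.

    Returns ``(frame, tau_result)``: per sink, the cohabitant /
    non-cohabitant / unknown proportions (summing to 1) plus the sink's
    cohabitant count, and the Kendall tau between cohabitant-sourced
    proportion and cohabitant count.  Sinks of single-occupant households
    have cohabitant proportion exactly 0.
    """
    households = metadata.households
    meta = metadata.frame
    rows = []
    for est in estimates:
        sink_ind = meta.loc[est.sink, "individual"]
        sink_house = households[sink_ind]
        coh = non = 0.0
        for name, prop in zip(est.sources[:-1], est.proportions[:-1]):
            if households.get(name) == sink_house:
                coh += prop
            else:
                non += prop
        unknown = float(est.proportions[-1])
        n_cohab = int(meta.loc[est.sink, "occupancy"]) - 1
        rows.append((est.sink, sink_ind, sink_house,
                     int(meta.loc[est.sink, "season"]), coh, non, unknown,
                     n_cohab))
    frame = pd.DataFrame(rows, columns=["sink", "individual", "household",
                                        "season", "cohabitant",
                                        "non_cohabitant", "unknown",
                                        "n_cohabitants"])
    if frame["n_cohabitants"].nunique() > 1 and len(frame) >= 3:
        tau = kendall(frame["n_cohabitants"], frame["cohabitant"])
    else:
        tau = TestResult(float("nan"), float("nan"), "kendall-tau-b",
                         (len(frame),), undefined=True)
    return frame, tau
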