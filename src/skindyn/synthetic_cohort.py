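"""Synthetic household-cohort generator.

Generates taxon count tables with the statistical structure the downstream
analyses assume: individual, household and seasonal effects on a latent
log-abundance scale, temporal noise whose magnitude grows with household
occupancy, cohabitant sharing, and a planted sparse precision matrix that
defines the true taxon-association network.  The generative model is
logistic-normal-multinomial:

    z_s = mu + (1 - rho) * a_i + rho * b_h + c_t + eps_s
    eps_s ~ MVN(0, sigma(occ_h)^2 * Omega^{-1}),  sigma(occ) = sigma0 * (1 + gamma*(occ-1))
    p_s = softmax(z_s);   counts_s ~ Multinomial(N_s, p_s)

with a_i ~ N(0, sigma_ind^2 I) per individual, b_h ~ N(0, sigma_house^2 I)
per household and c_t ~ N(0, sigma_season^2 I) per season.  The CLR-linear
latent structure matches the data model the network-inference stage assumes,
so the planted precision support is recoverable in principle.

Every draw is controlled by the config seed; identical config -> bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_io import CountTable, SampleMetadata, TaxonomyTable, SITES

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "simulate_tree",
    "planted_precision",
    "simulate_cohort",
    "simulate_negative_controls",
]

#: 11 households summing to 24 individuals, occupancy 1-6; four single-occupant
#: households mirror the cohort's four cohabitant-free households.
DEFAULT_OCCUPANCIES = (1, 1, 1, 1, 1, 2, 2, 2, 3, 4, 6)


@dataclass
class CohortConfig:
    """Design and effect sizes for one synthetic cohort.

    Effect sds are on the latent (log-abundance) scale.  ``gamma`` is the
    occupancy-noise slope: the temporal noise sd for a household of occupancy
    ``k`` is ``sigma0 * (1 + gamma * (k - 1))``, so gamma > 0 plants the
    occupancy -> temporal-variability association as a recoverable parameter.
    ``rho`` in [0, 1] shifts identity weight from the individual to the
    household effect, planting cohabitant sharing.
    """

    occupancies: tuple[int, ...] = DEFAULT_OCCUPANCIES
    n_seasons: int = 4
    sites: tuple[str, ...] = SITES
    n_taxa: int = 300
    median_reads: int = 20_000
    reads_sigma: float = 0.25  # lognormal sd of per-sample depth
    sigma_ind: float = 1.0
    sigma_house: float = 0.5
    sigma_season: float = 0.3
    sigma0: float = 0.2
    gamma: float = 0.3
    rho: float = 0.3
    network_density: float | None = None  # default 2 / n_taxa
    n_genera: int = 30
    n_contaminants: int = 3
    contaminant_abundance: float = 0.10
    seasonal_walk: bool = False  # c_t as random walk -> time-decay structure
    seed: int = 0

    @property
    def n_individuals(self) -> int:
        return int(sum(self.occupancies))

    def validate(self) -> None:
        for name in ("sigma_ind", "sigma_house", "sigma_season", "sigma0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if any(o < 1 for o in self.occupancies):
            raise ValueError("occupancies must be >= 1")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_contaminants > self.n_taxa:
            raise ValueError("more contaminants than taxa")
        if not 0 < self.contaminant_abundance < 1:
            raise ValueError("contaminant_abundance must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulated cohort."""

    precision: np.ndarray  # planted Omega (n_taxa x n_taxa)
    edges: set[tuple[str, str]]  # support of Omega, taxon-id pairs (a < b)
    edge_signs: dict[tuple[str, str], int]  # association sign (-Omega_ij sign)
    baselines: pd.DataFrame  # per-individual expected latent mean (taxa x ind)
    expected_composition: pd.DataFrame  # per-sample softmax(E[z_s]) (taxa x sample)
    gamma: float = 0.0
    rho: float = 0.0
    contaminants: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-edge in planted support")
            if (b, a) in self.edges:
                raise ValueError("planted support must store each pair once")


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Random rooted bifurcating tree with exponential(1) branch lengths.

    Built by random sequential pair-joining, so a tree on n tips has exactly
    2n - 1 nodes.  Deterministic given the seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i:04d}", length=float(rng.exponential(1.0)))
             for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def planted_precision(n_taxa: int, density: float, rng: np.random.Generator,
                      strength: float = 0.2) -> np.ndarray:
    """Sparse positive-definite precision matrix: chain backbone plus random
    hub edges, off-diagonals +-``strength`` with random sign, diagonal
    dominance enforced."""
    omega = np.zeros((n_taxa, n_taxa))
    signs = rng.choice([-1.0, 1.0], size=n_taxa - 1)
    for i in range(n_taxa - 1):  # chain backbone
        omega[i, i + 1] = omega[i + 1, i] = strength * signs[i]
    target_edges = max(0, int(round(density * n_taxa * (n_taxa - 1) / 2)))
    extra = target_edges - (n_taxa - 1)
    n_hubs = max(1, n_taxa // 30)
    hubs = rng.choice(n_taxa, size=n_hubs, replace=False)
    attempts = 0
    while extra > 0 and attempts < 50 * max(extra, 1):
        attempts += 1
        h = int(rng.choice(hubs))
        j = int(rng.integers(n_taxa))
        if j == h or omega[h, j] != 0:
            continue
        s = float(rng.choice([-1.0, 1.0]))
        omega[h, j] = omega[j, h] = strength * s
        extra -= 1
    row_mass = np.abs(omega).sum(axis=1)
    np.fill_diagonal(omega, row_mass + 0.1)  # diagonal dominance -> PD
    return omega


def _support(omega: np.ndarray, taxa: list[str]):
    edges, signs = set(), {}
    idx = np.argwhere(np.triu(omega, k=1) != 0)
    for i, j in idx:
        pair = (taxa[i], taxa[j])
        edges.add(pair)
        # partial correlation sign is the negated precision off-diagonal sign
        signs[pair] = int(np.sign(-omega[i, j]))
    return edges, signs


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def simulate_cohort(config: CohortConfig):
    """Draw one cohort.

    Returns ``(counts, metadata, taxonomy, tree, truth)``.  The default
    design is 24 individuals x 4 seasons x 5 sites = 480 samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_taxa
    taxa = [f"t{i:04d}" for i in range(p)]

    density = config.network_density
    if density is None:
        density = 2.0 / p
    omega = planted_precision(p, density, rng)
    cov = np.linalg.inv(omega)
    chol = np.linalg.cholesky(cov)

    mu = rng.normal(0.0, 1.0, size=p)  # uneven baseline composition
    households = [f"H{h:02d}" for h in range(len(config.occupancies))]
    individuals, ind_house = [], {}
    for h, occ in zip(households, config.occupancies):
        for k in range(occ):
            ind = f"{h}i{k}"
            individuals.append(ind)
            ind_house[ind] = h

    a = {i: rng.normal(0.0, config.sigma_ind, size=p) for i in individuals}
    b = {h: rng.normal(0.0, config.sigma_house, size=p) for h in households}
    if config.seasonal_walk:
        steps = rng.normal(0.0, config.sigma_season, size=(config.n_seasons, p))
        c = {t + 1: steps[: t + 1].sum(axis=0) for t in range(config.n_seasons)}
    else:
        c = {t + 1: rng.normal(0.0, config.sigma_season, size=p)
             for t in range(config.n_seasons)}

    occupancy = {h: occ for h, occ in zip(households, config.occupancies)}
    age_groups = {i: rng.choice(["adult", "elderly"], p=[0.7, 0.3])
                  for i in individuals}
    genders = {i: rng.choice(["F", "M"]) for i in individuals}

    rows, sample_ids, latent_means = [], [], []
    count_cols = []
    for ind in individuals:
        h = ind_house[ind]
        sigma_t = config.sigma0 * (1.0 + config.gamma * (occupancy[h] - 1))
        base = mu + (1 - config.rho) * a[ind] + config.rho * b[h]
        for t in range(1, config.n_seasons + 1):
            batch = f"B{t}"
            for site in config.sites:
                sid = f"{ind}_s{t}_{site}"
                eps = sigma_t * (chol @ rng.normal(size=p))
                z = base + c[t] + eps
                comp = _softmax(z[:, None])[:, 0]
                n_reads = int(np.round(config.median_reads
                                       * np.exp(rng.normal(0.0, config.reads_sigma))))
                n_reads = max(n_reads, 1)
                count_cols.append(rng.multinomial(n_reads, comp))
                sample_ids.append(sid)
                latent_means.append(_softmax((base + c[t])[:, None])[:, 0])
                rows.append((sid, ind, h, site, t, occupancy[h],
                             age_groups[ind], genders[ind], batch))

    counts = CountTable(taxa, sample_ids, np.column_stack(count_cols))
    meta_df = pd.DataFrame(
        rows,
        columns=["sample_id", "individual", "household", "site", "season",
                 "occupancy", "age_group", "gender", "batch"],
    ).set_index("sample_id")
    metadata = SampleMetadata(meta_df)

    genus_of = [f"g{(i * config.n_genera) // p:02d}" for i in range(p)]
    tax_df = pd.DataFrame(
        {
            "kingdom": "Bacteria",
            "phylum": [f"p{int(g[1:]) % 6}" for g in genus_of],
            "class": "c0", "order": "o0", "family": "f0",
            "genus": genus_of,
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    taxonomy = TaxonomyTable(tax_df)

    tree = simulate_tree(p, seed=int(rng.integers(2**31)))

    edges, signs = _support(omega, taxa)
    contaminants = taxa[-config.n_contaminants:] if config.n_contaminants else []
    truth = SyntheticTruth(
        precision=omega,
        edges=edges,
        edge_signs=signs,
        baselines=pd.DataFrame(
            {i: _softmax((mu + (1 - config.rho) * a[i]
                          + config.rho * b[ind_house[i]])[:, None])[:, 0]
             for i in individuals},
            index=taxa,
        ),
        expected_composition=pd.DataFrame(
            np.column_stack(latent_means), index=taxa, columns=sample_ids
        ),
        gamma=config.gamma,
        rho=config.rho,
        contaminants=list(contaminants),
    )
    return counts, metadata, taxonomy, tree, truth


def simulate_negative_controls(config: CohortConfig, n_controls: int,
                               seed: int) -> CountTable:
    """Negative-control samples: each contaminant taxon at the configured
    target relative abundance, every other taxon at a shared trace level."""
    config.validate()
    rng = np.random.default_rng(seed)
    p = config.n_taxa
    taxa = [f"t{i:04d}" for i in range(p)]
    comp = np.zeros(p)
    contaminants = list(range(p - config.n_contaminants, p))
    for i in contaminants:
        comp[i] = config.contaminant_abundance
    rest = 1.0 - comp.sum()
    if rest <= 0:
        raise ValueError("contaminant abundances exceed 1")
    others = [i for i in range(p) if i not in contaminants]
    comp[others] = rest / len(others)
    cols, ids = [], []
    for k in range(n_controls):
        n_reads = int(np.round(config.median_reads
                               * np.exp(rng.normal(0.0, config.reads_sigma))))
        cols.append(rng.multinomial(max(n_reads, 1), comp))
        ids.append(f"NC{k:02d}")
    data = np.column_stack(cols) if cols else np.zeros((p, 0), dtype=np.int64)
    return CountTable(taxa, ids, data)
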