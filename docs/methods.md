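# Methods

This note documents the models, estimators and numerical choices behind
`skindyn`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic-data tests do and do not
demonstrate.

## Synthetic cohort model

The generator emulates a household cohort: individuals i nested in
households h, sampled at 5 skin sites in each of 4 seasons t. For sample
s the latent log-abundance vector over p taxa is

    z_s = μ + (1 − ρ)·a_i + ρ·b_h + c_t + ε_s
    a_i ~ N(0, σ_ind² I),  b_h ~ N(0, σ_house² I),  c_t ~ N(0, σ_season² I)
    ε_s ~ MVN(0, σ(occ_h)² · Ω⁻¹),   σ(occ) = σ0 · (1 + γ·(occ − 1))

with composition p_s = softmax(z_s) and counts ~ Multinomial(N_s, p_s),
N_s lognormal with median 20 000 reads. The logistic-normal-multinomial
form is chosen deliberately: the network-inference stage assumes
CLR-linear structure, so the planted sparse precision matrix Ω is
recoverable in principle and serves as network ground truth.

Key parameters (latent log scale):

| parameter | default | role |
| --- | --- | --- |
| occupancies | (1,1,1,1,1,2,2,2,3,4,6) | 11 households, 24 individuals, range 1–6 |
| n_taxa | 300 | taxa after upstream OTU processing |
| median_reads | 20 000 | per-sample depth (lognormal, sd 0.25 logs) |
| σ_ind | 1.0 | individuality — the dominant effect in skin cohorts |
| σ_house | 0.5 | household effect |
| σ_season | 0.3 | season effect (`seasonal_walk` turns c_t into a random walk for time-decay structure) |
| σ0 | 0.2 | baseline temporal noise |
| γ | 0.3 | occupancy-noise slope: occupancy scales only the temporal noise sd, never the mean, so the occupancy–variability association is a single recoverable parameter |
| ρ | 0.3 | cohabitant sharing: weight moved from the individual to the household effect |

Ω is a chain backbone plus random hub edges, off-diagonal entries ±0.2
with random sign and a diagonally dominant diagonal (positive definite by
construction); target density 2/p. Taxa are partitioned into ~30
synthetic genera. Negative controls place each configured contaminant
taxon at 10 % expected relative abundance over a uniform trace
background.

What the generator does **not** emulate: sequence-level artifacts
(chimeras, batch-specific error), realistic taxon naming, site-specific
occupancy effects (γ is uniform across sites), and the heavy-tailed
abundance distributions of real skin communities. Tests passing on this
model show the estimators recover the structure they target under the
model's assumptions; they cannot certify behaviour on real data whose
violations of those assumptions matter.

## Filters and stability signatures

Filters run contaminants → minimum total reads → minimum prevalence.
The contaminant rule drops taxa whose **mean per-control** relative
abundance exceeds 5 % (strict inequality); a pooled-reads variant is a
flag. Read filters follow the two network analyses: ≥150 total reads per
taxon for per-individual networks, ≥10 for per-individual-per-season
networks; source tracking excludes taxa present in <10 % of samples.
Presence means count > 0.

Shannon diversity is the plug-in estimator in nats. Richness-corrected
estimators exist and were used in the motivating study; the plug-in form
is isolated behind `community_metrics.shannon` so an alternative can be
swapped without touching the CV machinery. CVs use the n−1 sd and are
reported as undefined (NaN), never 0, when the mean is 0 or fewer than
two seasons are available.

## Beta diversity

Weighted UniFrac is computed through a branch × taxon incidence matrix
(one construction per tree, shared across all samples and replicates):
raw d(A,B) = Σ_b ℓ_b |p_A(b) − p_B(b)|; the normalized variant divides by
Σ_tips depth_j (p_A(j)+p_B(j)). Raw is the default. PERMANOVA partitions
squared distances (pseudo-F with k−1 / N−k degrees of freedom); ANOSIM
ranks all pairs; both use seeded label permutations with
p = (1 + #{stat_perm ≥ stat_obs}) / (1 + n_perm) and default to 999
permutations. Season lag is |Δ season index| without wraparound (the
design spans a single year); time decay is the Spearman correlation of
similarity (1 − distance) with lag, so decay is negative. Family-wise
BH adjustment is applied within each named analysis (per-cell time decay,
site pairs, occupancy metrics).

## Association networks

Counts are CLR-transformed with pseudocount 1; each taxon column is
standardized and regressed on all others with an L1 penalty (coordinate
descent on the Gram matrix, tolerance 1e-6, ≤1000 sweeps; the StARS
subsample fits use tolerance 1e-5, which reproduces the same supports).
The penalty path has 20 log-spaced values from λ_max (largest absolute
off-diagonal covariance) down to 0.01·λ_max. StARS draws 50 subsamples of
size ⌊10√n⌋ capped at n−1, measures per-edge (OR-symmetrized) selection
frequencies f and total instability D(λ) = mean 2f(1−f), and selects the
smallest λ whose running supremum of D stays ≤ 0.05. Because that
supremum is monotone past its first crossing, the path walk stops at the
crossing — smaller penalties can never be selected, and the saturated
small-λ fits (expensive and statistically meaningless at n ≪ p) are
skipped. When the subsample size is n−1 only n distinct leave-one-out
subsamples exist; duplicates share one warm-started fit.

The final network refits neighborhoods at λ* on the full data,
symmetrizes with the OR rule (AND available), takes the mean of the
available directed coefficients as the edge weight (sign conflicts keep
the larger-magnitude direction, with a warning), and drops edges with
|weight| < 0.05. Weights are penalized regression coefficients — the
networks literature often calls them "correlations", which they are not.

Structure metrics binarize the network. Natural connectivity is
ln(mean exp λᵢ) of the 0/1 adjacency spectrum (via `logsumexp`);
robustness curves remove nodes in decreasing centrality order (static
ranking by default, re-ranking behind a flag; ties broken by node id) up
to 80 % of nodes, reporting nc_k/nc_0 — read as the nc ratio, the less
ambiguous reading of "relative proportion". On large graphs the curve is
evaluated on a coarsened removal grid (~40 spectral evaluations) rather
than after every removal. Graphlet orbits 0–14 are counted exactly:
3-node graphlets from neighbor pairs, 4-node graphlets by ESU
enumeration of connected 4-sets classified by within-subgraph degree.
GCD uses the 11 non-redundant orbits {0,1,2,4,5,6,7,8,9,10,11}, Spearman
correlation matrices over nodes with an all-ones dummy node guarding
constant columns, and the Euclidean norm of upper-triangle differences.
MDS is classical (Torgerson) with deterministic axis signs.

## Source tracking

Collapsed Gibbs sampling over per-read source assignments. A read of
taxon t goes to named source v with probability ∝
(m_tv + n_tv + α₁D) / (m_·v + n_·v + α₁DT) · (n_v + β); the Unknown
source has no observed counts and learns its distribution from its
assigned reads under a symmetric Dirichlet prior with per-taxon
concentration α₂ **unscaled** by depth — scaling α₂ by depth makes the
Unknown so diffuse that named sources absorb taxa no source contains,
inverting the intended behaviour on disjoint-support sinks. Defaults
α₁ = 0.001, α₂ = 0.1, β = 10, burn-in 100 sweeps, 10 recorded draws, 10
restarts, rarefaction depth 1000 follow the published defaults of the
Bayesian source-tracking method. The per-season design pools each
candidate individual's five site samples into one source environment
(per-sample sources behind a flag) and treats every sample of the focal
individual as a sink. The inner sweep is numba-compiled; all randomness
is drawn from a seeded generator outside the compiled code.

## Statistical toolkit

Mann-Whitney (exact U distribution via the Gaussian-binomial polynomial
for combined n ≤ 20 without ties, tie-corrected normal approximation with
continuity correction otherwise), Kruskal-Wallis with tie correction and
χ² p, a pairwise post hoc comparing |mean rank differences| against
z_{1−α/(k(k−1))}·√(N(N+1)/12·(1/nᵢ+1/nⱼ)), Spearman (t approximation),
Kendall τ-b (tie-corrected normal approximation) and Benjamini-Hochberg
step-up adjustment are implemented from their definitions; scipy and
statsmodels serve as independent oracles in the test suite, never as the
implementation. Tests are two-sided by default; ties take average ranks.

## Problem sizes in the test suite

Simulation-based checks use sizes chosen to give stable pass/fail
behaviour: type-I calibration uses 2000 null replicates (199 permutations
for the distance-based tests); planted-chain recovery uses p = 30,
n = 500; the GCD clustering check uses 25 replicate sets of 16 networks
inferred from 120-sample blocks (the cohort design itself provides only 5
samples per individual-season cell, which cannot support per-season
network recovery — the check targets structure discrimination, not StARS
at that cell size); occupancy-effect recovery uses 100 replicate cohorts
at the full 480-sample design for each γ. End-to-end determinism runs
the complete default pipeline twice and compares outputs byte for byte.
The default pipeline's network preset is the 24 per-individual networks;
the per-season preset (read filter 10) is available through
`network_group_by=("individual", "season")`.

## Known limitations

* The plug-in Shannon estimator is biased low at low depth; CV ratios are
  less affected but not immune.
* StARS with n = 20 samples per individual selects dense, weakly
  determined networks (the b = n−1 subsample cap leaves little subsample
  diversity); per-individual network edges should be read as exploratory,
  exactly as in small-n real cohorts.
* The Gibbs sampler's Unknown proportion depends on α₂; the default is
  calibrated for sharp unknowns and may under-report diffuse leakage.
* Graphlet enumeration is exact and scales with the number of connected
  4-sets; dense graphs beyond a few thousand edges become slow.
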