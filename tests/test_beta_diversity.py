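import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from skindyn.beta_diversity import (anosim, branch_matrix,
                                    correlate_with_occupancy,
                                    cross_site_temporal_correlation,
                                    permanova, relation_distance_summary,
                                    time_decay, weighted_unifrac)
from skindyn.data_io import DistanceMatrix
from skindyn.preprocess import RelAbundanceTable, to_relative_abundance
from skindyn.synthetic_cohort import CohortConfig, simulate_cohort, simulate_tree


def _tree(newick: str) -> TreeNode:
    tree = TreeNode.read([newick])
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def _brute_force_unifrac(tree, taxa, pa, pb, normalized=False):
    """Independent oracle: walk every branch, accumulate |dP| * length."""
    masses = dict(zip(taxa, zip(pa, pb)))
    total = 0.0
    denom = 0.0
    for node in tree.traverse(include_self=False):
        below = [t.name for t in node.tips()] or [node.name]
        wa = sum(masses.get(t, (0, 0))[0] for t in below)
        wb = sum(masses.get(t, (0, 0))[1] for t in below)
        total += (node.length or 0.0) * abs(wa - wb)
    if not normalized:
        return total
    for tip in tree.tips():
        depth = tip.accumulate_to_ancestor(tree)
        a, b = masses.get(tip.name, (0, 0))
        denom += depth * (a + b)
    return total / denom if denom else 0.0


class TestWeightedUnifrac:
    def test_two_tip_star_hand_value(self):
        tree = _tree("(A:1,B:1):0;")
        tab = RelAbundanceTable(["A", "B"], ["x", "y"],
                                np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert weighted_unifrac(tab, tree).between("x", "y") == \
            pytest.approx(2.0)
        assert weighted_unifrac(tab, tree, normalized=True).between("x", "y") \
            == pytest.approx(1.0)

    def test_identical_samples_zero(self):
        tree = _tree("((A:1,B:2):0.5,C:3):0;")
        col = np.array([0.2, 0.3, 0.5])
        tab = RelAbundanceTable(["A", "B", "C"], ["x", "y"],
                                np.column_stack([col, col]))
        assert weighted_unifrac(tab, tree).between("x", "y") == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for rep in range(10):
            tree = simulate_tree(8, seed=rep)
            taxa = [t.name for t in tree.tips()]
            profs = rng.dirichlet(np.ones(8), size=5).T
            tab = RelAbundanceTable(taxa, [f"s{i}" for i in range(5)], profs)
            for norm in (False, True):
                dm = weighted_unifrac(tab, tree, normalized=norm)
                for i, j in itertools.combinations(range(5), 2):
                    ref = _brute_force_unifrac(tree, taxa, profs[:, i],
                                               profs[:, j], norm)
                    assert dm.data[i, j] == pytest.approx(ref, abs=1e-10)

    def test_matches_scikit_bio(self):
        from skbio.diversity import beta_diversity
        tree = simulate_tree(10, seed=3)
        # skbio requires the tree rooted with length on root handled; give it
        # the same newick through its own parser
        taxa = [t.name for t in tree.tips()]
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(4, 10))
        counts[0, 0] += 1  # avoid empty sample
        tab = to_relative_abundance(
            __import__("skindyn.data_io", fromlist=["CountTable"]).CountTable(
                taxa, [f"s{i}" for i in range(4)], counts.T))
        ours = weighted_unifrac(tab, tree)
        ref = beta_diversity("weighted_unifrac", counts,
                             ids=[f"s{i}" for i in range(4)],
                             taxa=taxa, tree=tree, validate=True)
        assert np.allclose(ours.data, ref.data, atol=1e-10)

    def test_metric_properties_on_random_triples(self):
        tree = simulate_tree(12, seed=5)
        taxa = [t.name for t in tree.tips()]
        rng = np.random.default_rng(2)
        profs = rng.dirichlet(np.ones(12), size=30).T
        tab = RelAbundanceTable(taxa, [f"s{i}" for i in range(30)], profs)
        dm = weighted_unifrac(tab, tree)
        assert np.allclose(dm.data, dm.data.T)
        assert (dm.data >= 0).all()
        for _ in range(100):
            i, j, k = rng.choice(30, 3, replace=False)
            assert dm.data[i, k] <= dm.data[i, j] + dm.data[j, k] + 1e-12

    def test_raw_equals_normalized_times_factor(self):
        tree = simulate_tree(9, seed=8)
        taxa = [t.name for t in tree.tips()]
        rng = np.random.default_rng(3)
        profs = rng.dirichlet(np.ones(9), size=4).T
        tab = RelAbundanceTable(taxa, list("wxyz"), profs)
        raw = weighted_unifrac(tab, tree).data
        norm = weighted_unifrac(tab, tree, normalized=True).data
        _, lengths, depths = branch_matrix(tree, taxa)
        tipmass = depths @ profs
        factor = tipmass[:, None] + tipmass[None, :]
        assert np.allclose(raw, norm * factor, atol=1e-10)

    def test_missing_taxon_rejected(self):
        tree = _tree("(A:1,B:1):0;")
        tab = RelAbundanceTable(["A", "Z"], ["x"], np.array([[0.5], [0.5]]))
        with pytest.raises(ValueError, match="absent from tree"):
            weighted_unifrac(tab, tree)


class TestPermanovaAnosim:
    @pytest.fixture
    def toy_dm(self):
        d = np.array([[0.0, 0.1, 1.0, 1.0],
                      [0.1, 0.0, 1.0, 1.0],
                      [1.0, 1.0, 0.0, 0.1],
                      [1.0, 1.0, 0.1, 0.0]])
        return DistanceMatrix(list("abcd"), d)

    def test_pseudo_f_hand_value(self, toy_dm):
        r = permanova(toy_dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert r.statistic == pytest.approx(199.0)

    def test_anosim_perfect_separation(self, toy_dm):
        r = anosim(toy_dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert r.statistic == pytest.approx(1.0)

    def test_all_equal_distances_no_structure(self):
        d = np.ones((6, 6)) - np.eye(6)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        groups = ["a", "a", "a", "b", "b", "b"]
        rp = permanova(dm, groups, n_perm=199, seed=1)
        ra = anosim(dm, groups, n_perm=199, seed=1)
        assert np.isfinite(rp.statistic)
        assert rp.p_value > 0.9
        assert abs(ra.statistic) < 1e-12

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as sk_anosim
        from skbio.stats.distance import permanova as sk_permanova
        rng = np.random.default_rng(4)
        x = rng.random((12, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(12)]
        groups = ["a"] * 6 + ["b"] * 6
        ours_p = permanova(DistanceMatrix(ids, d), groups, 99, 0)
        ours_a = anosim(DistanceMatrix(ids, d), groups, 99, 0)
        ref_p = sk_permanova(SkbioDM(d, ids), grouping=groups, permutations=99)
        ref_a = sk_anosim(SkbioDM(d, ids), grouping=groups, permutations=99)
        assert ours_p.statistic == pytest.approx(ref_p["test statistic"])
        assert ours_a.statistic == pytest.approx(ref_a["test statistic"])

    def test_permutation_p_reproducible(self, toy_dm):
        g = ["g1", "g1", "g2", "g2"]
        p1 = permanova(toy_dm, g, n_perm=999, seed=11).p_value
        p2 = permanova(toy_dm, g, n_perm=999, seed=11).p_value
        assert p1 == p2

    def test_small_group_rejected(self, toy_dm):
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(toy_dm, ["g1", "g1", "g1", "g2"])


def _cell_metadata():
    rows = []
    for ind in ("i1", "i2"):
        for t in range(1, 5):
            rows.append((f"{ind}_s{t}", ind, "h1" if ind == "i1" else "h2",
                         "forehead", t, 1, "adult", "F", "B"))
    df = pd.DataFrame(rows, columns=["sample_id", "individual", "household",
                                     "site", "season", "occupancy",
                                     "age_group", "gender", "batch"])
    from skindyn.data_io import SampleMetadata
    return SampleMetadata(df.set_index("sample_id"))


class TestTimeDecay:
    def _dm_from_lag(self, fn):
        meta = _cell_metadata()
        ids = list(meta.frame.index)
        n = len(ids)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            a, b = meta.frame.iloc[i], meta.frame.iloc[j]
            if a["individual"] == b["individual"]:
                d[i, j] = d[j, i] = fn(abs(a["season"] - b["season"]))
            else:
                d[i, j] = d[j, i] = 0.9
        return DistanceMatrix(ids, d), meta

    def test_monotone_increase_gives_rho_minus_one(self):
        dm, meta = self._dm_from_lag(lambda lag: 0.1 * lag)
        out = time_decay(dm, meta)
        assert np.allclose(out["rho"].to_numpy(), -1.0)

    def test_lag_independent_gives_weak_rho(self):
        rng = np.random.default_rng(6)
        dm, meta = self._dm_from_lag(lambda lag: 0.5)
        out = time_decay(dm, meta)
        assert out["rho"].isna().all() or (out["rho"].abs() < 0.7).all()

    def test_seasonal_random_walk_produces_decay(self):
        medians = []
        for rep in range(6):
            config = CohortConfig(occupancies=(1, 1, 1), n_taxa=25,
                                  sites=("forehead",), sigma_season=0.8,
                                  sigma0=0.1, seasonal_walk=True,
                                  median_reads=3000, n_contaminants=0,
                                  seed=300 + rep)
            counts, meta, _, tree, _ = simulate_cohort(config)
            dm = weighted_unifrac(counts, tree)
            out = time_decay(dm, meta)
            medians.append(out["rho"].median())
        assert np.median(medians) < 0


class TestCrossSiteCorrelation:
    def test_identical_sites_rho_one(self, small_cohort):
        _, (counts, meta, _tax, tree, _truth) = small_cohort
        dm = weighted_unifrac(counts, tree)
        rho, p, padj = cross_site_temporal_correlation(dm, meta)
        sites = list(rho.index)
        # diagonal excluded by contract: upper triangle only
        assert np.isnan(rho.to_numpy()[np.tril_indices(len(sites))]).all()
        # identical site pair check: duplicate one site's distances
        assert rho.loc[sites[0], sites[1]] == \
            pytest.approx(rho.loc[sites[0], sites[1]])


class TestRelationSummary:
    def test_relation_ordering_with_sharing(self):
        hits = 0
        reps = 8
        for rep in range(reps):
            config = CohortConfig(occupancies=(2, 2, 1), n_taxa=25,
                                  sites=("forehead", "left_palm"),
                                  rho=0.8, median_reads=3000,
                                  n_contaminants=0, seed=400 + rep)
            counts, meta, _, tree, _ = simulate_cohort(config)
            dm = weighted_unifrac(counts, tree)
            grouped, kw, post = relation_distance_summary(dm, meta)
            med = {rel: np.median(grouped.values_for(rel))
                   for rel in grouped.RELATIONS}
            if med["same_individual"] < med["cohabitant"] < \
                    med["non_cohabitant"]:
                hits += 1
        assert hits >= int(0.75 * reps)

    def test_single_occupant_household_has_no_cohabitant_pairs(self):
        config = CohortConfig(occupancies=(1, 1), n_taxa=10, n_seasons=2,
                              sites=("forehead",), median_reads=500,
                              n_contaminants=0, seed=0)
        counts, meta, _, tree, _ = simulate_cohort(config)
        dm = weighted_unifrac(counts, tree)
        grouped, _, _ = relation_distance_summary(dm, meta)
        assert grouped.values_for("cohabitant").size == 0


class TestOccupancyCorrelation:
    def test_strictly_increasing_tau_one(self, small_cohort):
        _, (_c, meta, *_rest) = small_cohort
        occ = meta.occupancies
        house = meta.households
        vals = pd.DataFrame({
            "individual": list(house),
            "metric": [float(occ[house[i]]) * 2 + 1 for i in house],
        })
        out = correlate_with_occupancy(vals, meta)
        assert out.loc[0, "tau"] == pytest.approx(1.0)

    def test_constant_occupancy_flagged(self):
        config = CohortConfig(occupancies=(2, 2), n_taxa=8, n_seasons=2,
                              sites=("forehead",), median_reads=300,
                              n_contaminants=0, seed=1)
        _, meta, _, _, _ = simulate_cohort(config)
        vals = pd.DataFrame({"individual": list(meta.households),
                             "metric": [1.0, 2.0, 3.0, 4.0]})
        out = correlate_with_occupancy(vals, meta)
        assert bool(out.loc[0, "undefined"])
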