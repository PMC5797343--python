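import itertools

import networkx as nx
import numpy as np
import pytest

from skindyn.data_io import DistanceMatrix
from skindyn.network_structure import (NON_REDUNDANT_ORBITS,
                                       gcd_matrix,
                                       graphlet_correlation_distance,
                                       graphlet_orbit_counts, mds_embed,
                                       natural_connectivity,
                                       robustness_curve)

GRAPHLET_ATLAS = {
    # reference graphlets on 2-4 nodes: edge lists and orbit of each vertex
    "edge": ([(0, 1)], {0: 0, 1: 0}),
    "path3": ([(0, 1), (1, 2)], {0: 1, 1: 2, 2: 1}),
    "triangle": ([(0, 1), (1, 2), (0, 2)], {0: 3, 1: 3, 2: 3}),
    "path4": ([(0, 1), (1, 2), (2, 3)], {0: 4, 1: 5, 2: 5, 3: 4}),
    "claw": ([(0, 1), (0, 2), (0, 3)], {0: 7, 1: 6, 2: 6, 3: 6}),
    "cycle4": ([(0, 1), (1, 2), (2, 3), (3, 0)], {i: 8 for i in range(4)}),
    "paw": ([(0, 1), (1, 2), (2, 3), (3, 1)], {0: 9, 1: 11, 2: 10, 3: 10}),
    "diamond": ([(0, 1), (1, 2), (2, 3), (3, 0), (1, 3)],
                {0: 12, 1: 13, 2: 12, 3: 13}),
    "k4": (list(itertools.combinations(range(4), 2)), {i: 14 for i in range(4)}),
}


def _orbit_oracle(g: nx.Graph) -> np.ndarray:
    """Brute-force oracle: test every 2-/3-/4-subset against the reference
    graphlets by isomorphism and accumulate vertex orbits via the mapping."""
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    counts = np.zeros((len(nodes), 15), dtype=int)
    refs = []
    for name, (edges, orbit_of) in GRAPHLET_ATLAS.items():
        ref = nx.Graph(edges)
        refs.append((ref, orbit_of))
    for k in (2, 3, 4):
        for subset in itertools.combinations(nodes, k):
            sub = g.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            for ref, orbit_of in refs:
                if ref.number_of_nodes() != k:
                    continue
                gm = nx.algorithms.isomorphism.GraphMatcher(sub, ref)
                if gm.is_isomorphic():
                    for v, rv in gm.mapping.items():
                        counts[idx[v], orbit_of[rv]] += 1
                    break
    return counts


class TestNaturalConnectivity:
    def test_edgeless_graph_zero(self):
        g = nx.empty_graph(7)
        assert natural_connectivity(g) == pytest.approx(0.0)

    def test_k3_closed_form(self):
        expected = np.log((np.e**2 + 2 * np.exp(-1)) / 3)
        assert natural_connectivity(nx.complete_graph(3)) == \
            pytest.approx(expected, abs=1e-12)

    def test_strictly_increases_with_edge_addition(self):
        rng = np.random.default_rng(0)
        for rep in range(10):
            g = nx.gnp_random_graph(10, 0.3, seed=rep)
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            before = natural_connectivity(g)
            g.add_edge(*non_edges[rng.integers(len(non_edges))])
            assert natural_connectivity(g) > before

    def test_matches_independent_eigensolver(self):
        from scipy.linalg import eigvals
        for rep in range(5):
            g = nx.gnp_random_graph(12, 0.4, seed=100 + rep)
            a = nx.to_numpy_array(g)
            lam = np.real(eigvals(a))
            ref = np.log(np.exp(lam).mean())
            assert natural_connectivity(g) == pytest.approx(ref, abs=1e-9)

    def test_empty_node_set_rejected(self):
        with pytest.raises(ValueError):
            natural_connectivity(nx.empty_graph(0))


class TestRobustnessCurve:
    def test_star_hub_removed_first(self):
        c = robustness_curve(nx.star_graph(5), ordering="degree")
        assert c["removed"][0] == 0  # the hub
        assert c["relative_nc"][1] == pytest.approx(0.0)

    def test_complete_graph_ordering_irrelevant(self):
        cb = robustness_curve(nx.complete_graph(8), "betweenness")
        cd = robustness_curve(nx.complete_graph(8), "degree")
        assert np.allclose(cb["relative_nc"], cd["relative_nc"])

    def test_targeted_attack_beats_random_on_average(self):
        rng = np.random.default_rng(1)
        diffs = []
        for rep in range(8):
            g = nx.barabasi_albert_graph(25, 2, seed=rep)
            targeted = robustness_curve(g, "degree")["relative_nc"]
            h = g.copy()
            nodes = list(h.nodes)
            rng.shuffle(nodes)
            nc0 = natural_connectivity(g)
            random_curve = [1.0]
            for v in nodes[: int(0.8 * 25)]:
                h.remove_node(v)
                random_curve.append(natural_connectivity(h) / nc0)
            diffs.append(np.mean(random_curve) - np.mean(targeted))
        assert np.mean(diffs) > 0

    def test_edgeless_flagged_undefined(self):
        c = robustness_curve(nx.empty_graph(4), "degree")
        assert c["undefined"]


class TestOrbitCounts:
    def test_triangle_by_hand(self):
        _, c = graphlet_orbit_counts(nx.complete_graph(3))
        expected = np.zeros((3, 15), dtype=int)
        expected[:, 0] = 2
        expected[:, 3] = 1
        assert np.array_equal(c, expected)

    def test_path3_by_hand(self):
        nodes, c = graphlet_orbit_counts(nx.path_graph(3))
        by = dict(zip(nodes, c))
        assert by[1][0] == 2 and by[1][2] == 1
        assert by[0][0] == 1 and by[0][1] == 1
        assert by[2][0] == 1 and by[2][1] == 1

    @pytest.mark.parametrize("name", sorted(GRAPHLET_ATLAS))
    def test_each_graphlet_counts_itself(self, name):
        edges, orbit_of = GRAPHLET_ATLAS[name]
        nodes, c = graphlet_orbit_counts(nx.Graph(edges))
        for v, orb in orbit_of.items():
            i = nodes.index(v)
            assert c[i, orb] >= 1

    def test_oracle_equivalence_random_graphs(self):
        for rep in range(12):
            n = 8 + (rep % 4) * 4
            g = nx.gnp_random_graph(n, 0.25, seed=rep)
            nodes, ours = graphlet_orbit_counts(g)
            ref = _orbit_oracle(g)
            assert np.array_equal(ours, ref), f"mismatch on seed {rep}"

    def test_degree_and_edge_identities(self):
        g = nx.gnp_random_graph(20, 0.2, seed=7)
        nodes, c = graphlet_orbit_counts(g)
        assert c[:, 0].sum() == 2 * g.number_of_edges()
        assert c[:, 3].sum() == 3 * sum(nx.triangles(g).values()) // 3


class TestGCD:
    def test_identity_and_symmetry(self):
        g = nx.gnp_random_graph(12, 0.3, seed=0)
        h = nx.gnp_random_graph(12, 0.5, seed=1)
        assert graphlet_correlation_distance(g, g) == pytest.approx(0.0)
        assert graphlet_correlation_distance(g, h) == \
            pytest.approx(graphlet_correlation_distance(h, g))
        assert graphlet_correlation_distance(g, h) >= 0

    def test_isomorphic_relabeling_zero(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(14, 0.3, seed=3)
        relabel = dict(zip(g.nodes, rng.permutation(list(g.nodes)).tolist()))
        h = nx.relabel_nodes(g, relabel)
        assert graphlet_correlation_distance(g, h) == pytest.approx(0.0)

    def test_pseudometric_triangle_inequality(self):
        graphs = [nx.gnp_random_graph(10, p, seed=s)
                  for s, p in enumerate([0.2, 0.3, 0.4, 0.5, 0.6, 0.7])]
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c = rng.choice(len(graphs), 3, replace=False)
            dab = graphlet_correlation_distance(graphs[a], graphs[b])
            dbc = graphlet_correlation_distance(graphs[b], graphs[c])
            dac = graphlet_correlation_distance(graphs[a], graphs[c])
            assert dac <= dab + dbc + 1e-9

    def test_gcd_matrix_matches_pairwise_calls(self):
        nets = {f"g{i}": nx.gnp_random_graph(10, 0.3 + 0.1 * i, seed=i)
                for i in range(4)}
        dm = gcd_matrix(nets)
        for i, a in enumerate(nets):
            for j, b in enumerate(nets):
                if i < j:
                    assert dm.data[i, j] == pytest.approx(
                        graphlet_correlation_distance(nets[a], nets[b]))


class TestMDS:
    def test_equilateral_triangle_recovered(self):
        dm = DistanceMatrix(list("abc"), np.ones((3, 3)) - np.eye(3))
        xy = mds_embed(dm, k=2)
        dists = [np.linalg.norm(xy[i] - xy[j])
                 for i, j in itertools.combinations(range(3), 2)]
        assert np.allclose(dists, dists[0], atol=1e-9)

    def test_duplicate_points_coincide(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        dm = DistanceMatrix(list("abc"), d)
        xy = mds_embed(dm, k=1)
        assert np.allclose(xy[0], xy[1], atol=1e-9)

    def test_projection_contracts_distances(self):
        rng = np.random.default_rng(4)
        x = rng.random((8, 5))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(8)], d)
        xy = mds_embed(dm, k=2)
        for i, j in itertools.combinations(range(8), 2):
            assert np.linalg.norm(xy[i] - xy[j]) <= d[i, j] + 1e-9

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(5)
        x = rng.random((6, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        assert np.array_equal(mds_embed(dm, k=2), mds_embed(dm, k=2))

    def test_k_beyond_rank_rejected(self):
        dm = DistanceMatrix(list("ab"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            mds_embed(dm, k=2)
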