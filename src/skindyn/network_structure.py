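"""Structure dynamics of association networks.

All metrics operate on the binarized (unweighted, simple, undirected)
graph: spectral natural connectivity, robustness under targeted node
removal, exact graphlet orbit counts for the nine 2-4-node graphlets,
graphlet correlation distance (GCD-11), and classical MDS for embedding a
matrix of pairwise network distances.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .data_io import DistanceMatrix
from .network_inference import AssociationNetwork
from .stats_core import rankdata

__all__ = [
    "to_graph",
    "natural_connectivity",
    "robustness_curve",
    "graphlet_orbit_counts",
    "graphlet_correlation_matrix",
    "graphlet_correlation_distance",
    "gcd_matrix",
    "mds_embed",
    "NON_REDUNDANT_ORBITS",
]

#: The 11 non-redundant orbits of the 2-4-node graphlets used for GCD-11.
NON_REDUNDANT_ORBITS = (0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11)

N_ORBITS = 15


def to_graph(network) -> nx.Graph:
    """Binarized networkx graph from an AssociationNetwork (or passthrough)."""
    if isinstance(network, nx.Graph):
        return network
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.edges.keys())
    return g


def natural_connectivity(network) -> float:
    """ln of the average exponentiated adjacency eigenvalue.

    A spectral proxy for robustness: counts closed walks of all lengths
    (weighted 1/k!), i.e. the redundancy of alternative paths.  Edgeless
    graphs give 0.
    """
    g = to_graph(network)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty node set")
    a = nx.to_numpy_array(g, dtype=float)
    eig = np.linalg.eigvalsh(a)
    return float(logsumexp(eig) - np.log(n))


def robustness_curve(network, ordering: str = "betweenness",
                     max_fraction: float = 0.8,
                     recompute: bool = False,
                     eval_every: int = 1) -> dict:
    """Relative natural connectivity under targeted node removal.

    Nodes are removed one at a time, up to floor(max_fraction * n), in
    decreasing order of the chosen centrality (ties by node id).  The
    ranking is computed once on the intact graph by default; ``recompute``
    re-ranks after every removal.  ``eval_every`` coarsens the evaluation
    grid: connectivity is recorded every that many removals (plus the final
    point), which bounds the spectral cost on large graphs.  Returns a dict
    with the removal-fraction grid, nc_k / nc_0 values, the ordering tag,
    and an ``undefined`` flag for edgeless graphs.
    """
    g = to_graph(network).copy()
    n0 = g.number_of_nodes()
    if n0 < 2:
        raise ValueError("need >= 2 nodes")
    if ordering not in ("betweenness", "degree"):
        raise ValueError("ordering must be 'betweenness' or 'degree'")
    nc0 = natural_connectivity(g)
    out = {"ordering": ordering, "fractions": [0.0], "relative_nc": [1.0],
           "removed": [], "undefined": nc0 == 0.0}
    if out["undefined"]:
        return out

    def rank(h):
        cent = (nx.betweenness_centrality(h) if ordering == "betweenness"
                else dict(h.degree()))
        return sorted(h.nodes, key=lambda v: (-cent[v], v))

    order = rank(g)
    n_remove = int(np.floor(max_fraction * n0))
    for k in range(n_remove):
        victim = rank(g)[0] if recompute else order[k]
        g.remove_node(victim)
        out["removed"].append(victim)
        if (k + 1) % eval_every == 0 or k + 1 == n_remove:
            out["fractions"].append((k + 1) / n0)
            out["relative_nc"].append(natural_connectivity(g) / nc0)
    return out


# ---------------------------------------------------------------------------
# graphlet orbits


def _orbit_counts_4(sub_adj: np.ndarray):
    """Classify a connected 4-node induced subgraph; return the orbit id of
    each of its 4 vertices (by within-subgraph degree)."""
    deg = sub_adj.sum(axis=1).astype(int)
    m = int(deg.sum()) // 2
    if m == 3:
        if deg.max() == 3:  # star K_{1,3}: center orbit 7, leaves orbit 6
            return [7 if d == 3 else 6 for d in deg]
        # path P4: ends orbit 4, middles orbit 5
        return [4 if d == 1 else 5 for d in deg]
    if m == 4:
        if deg.max() == 2:  # cycle C4
            return [8, 8, 8, 8]
        # paw (tailed triangle): tail end orbit 9, plain triangle vertices
        # orbit 10, triangle vertex carrying the tail orbit 11
        return [{1: 9, 2: 10, 3: 11}[d] for d in deg]
    if m == 5:  # diamond: degree-2 vertices orbit 12, degree-3 orbit 13
        return [12 if d == 2 else 13 for d in deg]
    return [14, 14, 14, 14]  # K4


def graphlet_orbit_counts(network) -> tuple[list, np.ndarray]:
    """Exact per-node counts of orbits 0-14 over all connected induced
    2-4-node subgraphs.

    2- and 3-node graphlets are counted from edges and neighbor pairs; the
    connected 4-sets are enumerated without duplication by the ESU
    (exhaustive subgraph enumeration) scheme.  Returns
    ``(nodes, counts)`` with counts of shape (n_nodes, 15).
    """
    g = to_graph(network)
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    counts = np.zeros((n, N_ORBITS), dtype=np.int64)
    adj = {v: set(g.neighbors(v)) for v in nodes}

    for v in nodes:
        counts[index[v], 0] = len(adj[v])  # orbit 0 = degree

    # 3-node graphlets: enumerate unordered neighbor pairs of each center
    for v in nodes:
        for u, w in itertools.combinations(sorted(adj[v]), 2):
            if w in adj[u]:  # triangle; counted once from each vertex
                counts[index[v], 3] += 1
            else:  # path, v is the middle
                counts[index[v], 2] += 1
                counts[index[u], 1] += 1
                counts[index[w], 1] += 1

    # 4-node graphlets via ESU over connected 4-subsets
    order = {v: i for i, v in enumerate(nodes)}

    def extend(subgraph, extension, root):
        if len(subgraph) == 4:
            idx4 = [index[v] for v in subgraph]
            sub = np.zeros((4, 4))
            for a, b in itertools.combinations(range(4), 2):
                if subgraph[b] in adj[subgraph[a]]:
                    sub[a, b] = sub[b, a] = 1.0
            for pos, orb in zip(idx4, _orbit_counts_4(sub)):
                counts[pos, orb] += 1
            return
        ext = sorted(extension)
        for i, w in enumerate(ext):
            excl = set(ext[i + 1:])
            new_ext = excl | {u for u in adj[w]
                              if order[u] > order[root] and u not in subgraph
                              and all(u not in adj[s] for s in subgraph)}
            extend(subgraph + [w], new_ext, root)

    for v in nodes:
        ext = {u for u in adj[v] if order[u] > order[v]}
        extend([v], ext, v)

    return nodes, counts


def graphlet_correlation_matrix(network,
                                orbits=NON_REDUNDANT_ORBITS) -> np.ndarray:
    """Spearman correlation matrix of the selected orbit counts across
    nodes, with one all-ones dummy node appended to guard constant columns."""
    _, counts = graphlet_orbit_counts(network)
    sel = counts[:, list(orbits)].astype(float)
    sel = np.vstack([sel, np.ones(len(orbits))])
    ranks = np.column_stack([rankdata(sel[:, j]) for j in range(sel.shape[1])])
    return np.corrcoef(ranks, rowvar=False)


def graphlet_correlation_distance(net_a, net_b,
                                  orbits=NON_REDUNDANT_ORBITS) -> float:
    """GCD: Euclidean norm of the difference of the strict upper triangles
    of the two graphlet correlation matrices."""
    ca = graphlet_correlation_matrix(net_a, orbits)
    cb = graphlet_correlation_matrix(net_b, orbits)
    iu = np.triu_indices(len(orbits), 1)
    return float(np.linalg.norm(ca[iu] - cb[iu]))


def gcd_matrix(networks: dict) -> DistanceMatrix:
    """Pairwise GCD between a labelled collection of networks."""
    ids = list(networks)
    mats = {k: graphlet_correlation_matrix(networks[k]) for k in ids}
    iu = np.triu_indices(len(NON_REDUNDANT_ORBITS), 1)
    vecs = np.array([mats[k][iu] for k in ids])
    diff = vecs[:, None, :] - vecs[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d)


def mds_embed(dm: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS.

    Double-centers the squared distances and embeds on the top-k
    eigenvectors scaled by sqrt(eigenvalue).  Axis signs are fixed by
    making the first nonzero loading of each axis positive, so the
    embedding is fully deterministic.
    """
    d2 = dm.data**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    rank = int((eigval > 1e-10).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds embedding rank {rank}")
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0.0, None))
    for axis in range(k):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords
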