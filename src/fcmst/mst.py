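"""Maximum-weight spanning trees of FC matrices and their topology metrics.

The spanning tree that maximises total connectivity weight is extracted
with Kruskal's algorithm (edges considered in descending weight, cycles
rejected via union-find).  Working on raw FC weights rather than 1-w
distances keeps the tree's ``mean`` metric on the connectivity scale.

Eight scalar descriptors summarise each tree of N nodes and M = N-1 edges:

==============  ==========================================================
leaf_number L   count of degree-1 nodes (2 = path ... N-1 = star)
leaf_fraction   L / M
diameter d      longest hop-count shortest path
hierarchy Th    L / (2 M Bmax), Bmax = max normalised node betweenness;
                0.5 for a star, -> 0 for a long path
kappa           degree divergence <k^2>/<k>; hub-sensitive
assortativity R Pearson correlation of endpoint degrees over the
                symmetrised edge list (NaN when degenerate)
teff            1 - d / (N - L + 1); how close the diameter is to its
                minimum given the leaf count, in [0, 1]
asp             average hop-count shortest path over all unordered pairs
mean_weight     mean of the M edge weights (FC units)
==============  ==========================================================

Distances are hop counts (every edge counts 1).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "SpanningTree",
    "MSTMetrics",
    "METRIC_NAMES",
    "kruskal_max_spanning_tree",
    "mst_metrics",
    "tree_from_prufer",
    "enumerate_labelled_trees",
]


@dataclass
class SpanningTree:
    """A tree on ``n_nodes`` labelled nodes: exactly n_nodes - 1 edges."""

    n_nodes: int
    edges: list  # of (i, j, weight) with i < j
    node_labels: tuple = ()

    def __post_init__(self):
        if len(self.edges) != self.n_nodes - 1:
            raise InvalidParameterError(
                f"{len(self.edges)} edges for {self.n_nodes} nodes; "
                "a spanning tree needs exactly n_nodes - 1"
            )
        g = self.to_networkx()
        if g.number_of_nodes() != self.n_nodes or not nx.is_connected(g):
            raise InvalidParameterError("edge list is not a connected tree")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


class _UnionFind:
    """Disjoint sets with path compression and union by rank."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.rank[ra] += self.rank[ra] == self.rank[rb]
        return True


def kruskal_max_spanning_tree(weights: np.ndarray, node_labels=()) -> SpanningTree:
    """Maximum-weight spanning tree by Kruskal's algorithm.

    Edges are taken in descending weight; an edge closing a cycle is
    refused.  Ties are broken deterministically by ascending (i, j) node
    index, so equal-weight inputs give a platform-independent tree.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise InvalidParameterError("weights must be a square matrix")
    n = w.shape[0]
    if n < 2:
        raise InvalidParameterError("need at least 2 nodes")
    if not np.isfinite(w).all():
        raise InvalidParameterError("weights must be finite")
    if not np.allclose(w, w.T, atol=1e-10):
        raise InvalidParameterError("weights must be symmetric")

    candidates = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (-w[e[0], e[1]], e[0], e[1]),
    )
    uf = _UnionFind(n)
    edges = []
    for i, j in candidates:
        if uf.union(i, j):
            edges.append((i, j, float(w[i, j])))
            if len(edges) == n - 1:
                break
    return SpanningTree(n, edges, tuple(node_labels))


@dataclass
class MSTMetrics:
    """The eight scalar topology descriptors of a spanning tree."""

    leaf_number: float
    leaf_fraction: float
    diameter: float
    hierarchy: float
    kappa: float
    assortativity_r: float
    teff: float
    asp: float
    mean_weight: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: The eight descriptors reported per tree in metric tables and statistics.
#: ``leaf_fraction`` is carried on :class:`MSTMetrics` for convenience but is
#: not reported separately: it is leaf_number / (N - 1), so with a fixed
#: montage it duplicates the leaf number exactly and would double-count in
#: any joint analysis.
METRIC_NAMES = (
    "leaf_number",
    "diameter",
    "hierarchy",
    "kappa",
    "assortativity_r",
    "teff",
    "asp",
    "mean_weight",
)


def mst_metrics(tree: SpanningTree) -> MSTMetrics:
    """Compute all eight topology metrics of a spanning tree (N >= 3).

    The assortativity R is NaN when the endpoint-degree correlation is
    degenerate; callers are expected to exclude NaN from statistics.
    """
    n = tree.n_nodes
    if n < 3:
        raise InvalidParameterError(
            "metrics need N >= 3 (assortativity and hierarchy degenerate)"
        )
    g = tree.to_networkx()
    m = n - 1

    deg = tree.degrees()
    leaf_number = int((deg == 1).sum())
    leaf_fraction = leaf_number / m
    kappa = float((deg**2).sum() / deg.sum())

    # Hop-count distances: unweighted BFS from every node.
    dist = dict(nx.all_pairs_shortest_path_length(g))
    pair_dists = [
        dist[i][j] for i in range(n) for j in range(i + 1, n)
    ]
    diameter = int(max(pair_dists))
    asp = float(np.mean(pair_dists))

    teff = 1.0 - diameter / (n - leaf_number + 1)

    bmax = max(nx.betweenness_centrality(g, normalized=True).values())
    hierarchy = leaf_number / (2.0 * m * bmax)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.degree_pearson_correlation_coefficient(g)
    if not math.isfinite(r):
        warnings.warn(
            "degree assortativity undefined for this tree; reporting NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        r = float("nan")

    mean_weight = float(np.mean([w for _, _, w in tree.edges]))
    return MSTMetrics(
        leaf_number=float(leaf_number),
        leaf_fraction=float(leaf_fraction),
        diameter=float(diameter),
        hierarchy=float(hierarchy),
        kappa=kappa,
        assortativity_r=float(r),
        teff=float(teff),
        asp=asp,
        mean_weight=mean_weight,
    )


def tree_from_prufer(seq, weights: np.ndarray | None = None) -> SpanningTree:
    """Decode a Prüfer sequence of length N-2 into a labelled tree on N nodes."""
    import heapq

    seq = list(seq)
    n = len(seq) + 2
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for v in seq:
        leaf = heapq.heappop(leaves)
        edges.append((min(leaf, v), max(leaf, v)))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((min(u, v), max(u, v)))
    wfun = (lambda i, j: 1.0) if weights is None else (
        lambda i, j: float(weights[i, j])
    )
    return SpanningTree(n, [(i, j, wfun(i, j)) for i, j in edges])


def enumerate_labelled_trees(n: int, weights: np.ndarray | None = None):
    """Yield all n^(n-2) labelled trees on n nodes via Prüfer sequences."""
    if n < 2:
        raise InvalidParameterError("need n >= 2")
    if n == 2:
        w = 1.0 if weights is None else float(weights[0, 1])
        yield SpanningTree(2, [(0, 1, w)])
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        yield tree_from_prufer(seq, weights)
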