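"""Independent brute-force oracles, deliberately decoupled from the package.

Everything here recomputes quantities from first principles (direct DFT,
hand-rolled BFS, direct Prüfer decoding) so that tests compare two
genuinely different routes to the same number.
"""

from __future__ import annotations

import numpy as np


def dft_analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic signal built directly from the DFT definition.

    Zero out negative frequencies, double positive ones, keep DC and
    Nyquist; one channel (1-D input) at a time.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    spectrum = np.fft.fft(x)
    weights = np.zeros(n)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[n // 2] = 1.0
        weights[1 : n // 2] = 2.0
    else:
        weights[1 : (n + 1) // 2] = 2.0
    return np.fft.ifft(spectrum * weights)


def prufer_decode(seq) -> list:
    """Direct Prüfer decoding via remaining-occurrence counts.

    A node is an eligible leaf once it no longer occurs in the rest of the
    sequence; the smallest eligible leaf is attached to the current symbol.
    """
    seq = list(seq)
    n = len(seq) + 2
    remaining = [0] * n
    for v in seq:
        remaining[v] += 1
    eligible = {i for i in range(n) if remaining[i] == 0}
    edges = []
    for v in seq:
        leaf = min(eligible)
        eligible.remove(leaf)
        edges.append((min(leaf, v), max(leaf, v)))
        remaining[v] -= 1
        if remaining[v] == 0:
            eligible.add(v)
    u, w = sorted(eligible)
    edges.append((u, w))
    return edges


def all_tree_edge_arrays(n: int) -> np.ndarray:
    """(n^(n-2), n-1, 2) array of edges of every labelled tree on n nodes."""
    import itertools

    trees = []
    if n == 2:
        return np.array([[[0, 1]]])
    for seq in itertools.product(range(n), repeat=n - 2):
        trees.append(prufer_decode(seq))
    return np.asarray(trees)


def max_spanning_tree_weight_bruteforce(w: np.ndarray, edge_arrays=None) -> float:
    """Maximum total weight over every labelled spanning tree."""
    n = w.shape[0]
    if edge_arrays is None:
        edge_arrays = all_tree_edge_arrays(n)
    totals = w[edge_arrays[:, :, 0], edge_arrays[:, :, 1]].sum(axis=1)
    return float(totals.max())


def bfs_hop_distances(n: int, edges) -> np.ndarray:
    """All-pairs hop distances of a tree by hand-rolled BFS from every node."""
    adj = [[] for _ in range(n)]
    for e in edges:
        i, j = int(e[0]), int(e[1])
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full((n, n), -1, dtype=int)
    for src in range(n):
        dist[src, src] = 0
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[src, v] < 0:
                        dist[src, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist
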