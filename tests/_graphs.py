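"""Shared graph helpers: hand-built networks and exhaustive partition search.

The brute-force minimum description length is the independent oracle the
greedy clusterer is checked against; it enumerates every set partition of
the node set (Bell(8) = 4140 at most) and evaluates the map equation on
each, so it shares no code path with the optimizer.
"""

import numpy as np
from scipy import sparse

from bioregionet import bionet


def net_from_edges(n, edges):
    """Wrap an arbitrary undirected edge list in the network container (node
    kinds are irrelevant for the clustering math)."""
    rows = [u for u, v in edges] + [v for u, v in edges]
    cols = [v for u, v in edges] + [u for u, v in edges]
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return bionet.BipartiteNetwork(
        [], np.arange(n), adj.indptr.astype(np.int64), adj.indices.astype(np.int64)
    )


def set_partitions(n):
    """All set partitions of range(n) in restricted-growth-string form."""
    if n == 1:
        yield [0]
        return
    for p in set_partitions(n - 1):
        for k in range(max(p) + 2):
            yield p + [k]


def brute_force_min_length(net):
    """Exhaustive minimum of the map equation over all partitions."""
    best = np.inf
    best_p = None
    for p in set_partitions(net.n_nodes):
        length = bionet.map_equation_length(net, np.array(p))
        if length < best:
            best, best_p = length, p
    return best, np.array(best_p)


FIXTURE_GRAPHS = {
    "cycle4": (4, [(0, 1), (1, 2), (2, 3), (3, 0)]),
    "path5": (5, [(0, 1), (1, 2), (2, 3), (3, 4)]),
    "star5": (6, [(0, i) for i in range(1, 6)]),
    "two_triangles_bridge": (6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]),
    "k4": (4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]),
    "two_k22_disconnected": (8, [(0, 2), (0, 3), (1, 2), (1, 3), (4, 6), (4, 7), (5, 6), (5, 7)]),
    "biclique_k23": (5, [(0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4)]),
    "barbell": (8, [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (4, 6), (5, 6), (6, 7)]),
}
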