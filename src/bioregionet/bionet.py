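"""Bipartite biogeographical network: build, cluster, filter, fidelity.

Species and grid cells are the two node sets; an undirected, unweighted edge
records each presence. Regions are modules of the partition minimizing the
two-level map equation (description length, in bits, of a random walk on the
network), found by greedy node moves with Louvain-style aggregation and many
seeded restarts. Modules with fewer than ``min_nodes`` nodes are treated as
anecdotal and discarded; surviving modules become regions numbered by
decreasing size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from ._mapeq import optimize_level
from .occurrences import PresenceMatrix
from .synthetic import EnvField

__all__ = [
    "BipartiteNetwork",
    "Partition",
    "RegionAssignment",
    "build_network",
    "map_equation_length",
    "infomap_cluster",
    "filter_minor_clusters",
    "species_fidelity",
    "label_regions",
    "export_network",
    "import_network",
]


@dataclass
class BipartiteNetwork:
    """Species-site incidence graph. Node ids: species first (0..S-1), then
    sites (S..S+C-1); ``indptr``/``indices`` hold the CSR adjacency."""

    species: list[str]
    cells: np.ndarray
    indptr: np.ndarray
    indices: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.cells)

    @property
    def n_nodes(self) -> int:
        return self.n_species + self.n_sites

    @property
    def n_edges(self) -> int:
        return self.indices.size // 2

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def node_names(self) -> list[str]:
        return list(self.species) + [f"cell_{c}" for c in self.cells]

    def node_kinds(self) -> np.ndarray:
        return np.array(["species"] * self.n_species + ["site"] * self.n_sites)


@dataclass
class Partition:
    """Node-to-module assignment with its description length in bits."""

    modules: np.ndarray  # module id per node, 0-based contiguous
    description_length: float
    n_modules: int
    seed: int
    run_index: int  # restart that produced the winning partition

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.modules, minlength=self.n_modules)


@dataclass
class RegionAssignment:
    """Major regions after the minor-cluster filter, numbered 1..K by
    decreasing node count. Unassigned nodes map to 0 (minor cluster)."""

    module_to_region: dict[int, int]
    species_region: pd.Series  # species id -> region (0 = unassigned)
    cell_region: pd.Series  # cell id -> region (0 = unassigned)
    region_sizes: dict[int, int]
    min_nodes: int

    @property
    def regions(self) -> list[int]:
        return sorted(self.region_sizes)

    def cells_of(self, region: int) -> np.ndarray:
        return self.cell_region.index[self.cell_region == region].to_numpy()


def build_network(pm: PresenceMatrix) -> BipartiteNetwork:
    """One undirected edge per presence; node degrees equal the presence
    matrix row/column sums."""
    if pm.matrix.nnz == 0:
        raise ValueError("presence matrix is empty")
    s = len(pm.species)
    coo = pm.matrix.tocoo()
    rows = np.concatenate([coo.row, coo.col + s])
    cols = np.concatenate([coo.col + s, coo.row])
    n = s + len(pm.cells)
    adj = sparse.csr_matrix((np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n))
    return BipartiteNetwork(
        list(pm.species), np.asarray(pm.cells), adj.indptr.astype(np.int64), adj.indices.astype(np.int64)
    )


def _plogp(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 1e-300
    out[pos] = x[pos] * np.log2(x[pos])
    return out


def map_equation_length(net: BipartiteNetwork, partition) -> float:
    """Two-level map equation L, in bits, for an undirected unweighted walk.

    With node visit rates p_a = deg(a)/2E, module exit rates
    q_i = (boundary edges of module i)/2E and q = sum_i q_i:

        L = q H(Q) + sum_i (q_i + p_i) H(P_i)

    which expands to q log q - 2 sum plogp(q_i) + sum plogp(q_i + p_i)
    - sum plogp(p_a) (all logs base 2). A single-module partition therefore
    returns the entropy of the node visit rates.
    """
    modules = _as_module_array(net, partition)
    deg = net.degrees.astype(float)
    two_e = deg.sum()
    p = deg / two_e
    k = int(modules.max()) + 1
    if np.any(np.bincount(modules, minlength=k) == 0):
        raise ValueError("partition contains an empty module")
    mod_p = np.bincount(modules, weights=p, minlength=k)
    # internal flow: arcs whose endpoints share a module
    src = np.repeat(np.arange(net.n_nodes), np.diff(net.indptr))
    same = modules[src] == modules[net.indices]
    internal = np.bincount(modules[src][same], minlength=k) / two_e
    q = mod_p - internal
    q = np.maximum(q, 0.0)
    return float(_plogp(q.sum()) - 2 * _plogp(q).sum() + _plogp(q + mod_p).sum() - _plogp(p).sum())


def _as_module_array(net: BipartiteNetwork, partition) -> np.ndarray:
    if isinstance(partition, Partition):
        return partition.modules
    if isinstance(partition, dict):
        names = net.node_names()
        missing = [x for x in names if x not in partition]
        if missing:
            raise ValueError(f"partition does not cover all nodes (missing {missing[:3]}...)")
        raw = np.array([partition[x] for x in names])
        _, arr = np.unique(raw, return_inverse=True)
        return arr
    arr = np.asarray(partition, dtype=np.int64)
    if arr.shape != (net.n_nodes,):
        raise ValueError("partition must assign every node exactly once")
    _, arr = np.unique(arr, return_inverse=True)
    return arr


def _aggregate(indptr, indices, phi, node_p, node_self, modules):
    """Condense modules into super-nodes, preserving flows exactly."""
    _, mods = np.unique(modules, return_inverse=True)
    k = mods.max() + 1
    src = np.repeat(np.arange(node_p.size), np.diff(indptr))
    msrc, mdst = mods[src], mods[indices]
    internal = msrc == mdst
    new_self = np.bincount(mods, weights=node_self, minlength=k)
    new_self += np.bincount(msrc[internal], weights=phi[internal], minlength=k)
    new_p = np.bincount(mods, weights=node_p, minlength=k)
    ext = ~internal
    adj = sparse.csr_matrix((phi[ext], (msrc[ext], mdst[ext])), shape=(k, k))
    adj.sum_duplicates()
    return (
        adj.indptr.astype(np.int64),
        adj.indices.astype(np.int64),
        adj.data.astype(np.float64),
        new_p,
        new_self,
        mods,
    )


def _one_run(net: BipartiteNetwork, seed: int) -> np.ndarray:
    """Single restart: greedy moves + aggregation until the module set is
    stable. Returns the module array over the original nodes."""
    deg = net.degrees.astype(float)
    two_e = deg.sum()
    indptr, indices = net.indptr, net.indices
    phi = np.full(indices.size, 1.0 / two_e)  # per-arc flow = weight/2E
    node_p = deg / two_e
    node_self = np.zeros(net.n_nodes)
    full = np.arange(net.n_nodes)
    level = 0
    while True:
        mods, _ = optimize_level(indptr, indices, phi, node_p, node_self, (seed + 7919 * level) % 2**31)
        k = np.unique(mods).size
        if k == node_p.size:  # no move improved: stable
            break
        indptr, indices, phi, node_p, node_self, mods = _aggregate(
            indptr, indices, phi, node_p, node_self, mods
        )
        full = mods[full]
        if k == 1:
            break
        level += 1
    _, full = np.unique(full, return_inverse=True)
    return full


def infomap_cluster(net: BipartiteNetwork, n_runs: int = 100, seed: int = 0) -> Partition:
    """Best-of-``n_runs`` greedy minimization of the map equation.

    Each restart starts from singleton modules and uses its own sub-seed;
    the partition with the shortest description length wins, with ties going
    to the earliest restart (deterministic for a given seed).
    """
    best_l = np.inf
    best_mods = None
    best_run = -1
    for r in range(n_runs):
        sub = (seed * 1_000_003 + r) % 2**31
        mods = _one_run(net, sub)
        l_run = map_equation_length(net, mods)
        if l_run < best_l - 1e-12:
            best_l, best_mods, best_run = l_run, mods, r
    # renumber modules by decreasing size for stable downstream ids
    sizes = np.bincount(best_mods)
    order = np.argsort(-sizes, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    best_mods = rank[best_mods]
    return Partition(
        modules=best_mods,
        description_length=best_l,
        n_modules=int(best_mods.max()) + 1,
        seed=seed,
        run_index=best_run,
    )


def filter_minor_clusters(partition: Partition | np.ndarray, min_nodes: int = 20, net: BipartiteNetwork | None = None) -> RegionAssignment:
    """Discard modules with fewer than ``min_nodes`` nodes and renumber the
    survivors 1..K by decreasing node count (region 1 = largest)."""
    if net is None:
        raise ValueError("net is required to map node ids back to species/cells")
    modules = partition.modules if isinstance(partition, Partition) else np.asarray(partition)
    sizes = np.bincount(modules)
    major = np.flatnonzero(sizes >= min_nodes)
    if major.size == 0:
        warnings.warn("all modules are minor; empty region assignment", stacklevel=2)
    order = major[np.argsort(-sizes[major], kind="stable")]
    module_to_region = {int(m): i + 1 for i, m in enumerate(order)}
    region = np.array([module_to_region.get(int(m), 0) for m in modules])
    s = net.n_species
    species_region = pd.Series(region[:s], index=net.species, name="region")
    cell_region = pd.Series(region[s:], index=pd.Index(net.cells, name="cell_id"), name="region")
    region_sizes = {module_to_region[int(m)]: int(sizes[m]) for m in order}
    return RegionAssignment(module_to_region, species_region, cell_region, region_sizes, min_nodes)


def species_fidelity(partition, pm: PresenceMatrix, net: BipartiteNetwork | None = None, assignment: RegionAssignment | None = None) -> pd.DataFrame:
    """Share of each species' presence cells falling in each cluster:
    F_i(region) = presences of i in the region / total presences of i.

    Computed over all modules before the minor-cluster discard, so each row
    sums to 1. If ``assignment`` is given, module columns are relabelled to
    regions, with all minor modules pooled under column 0.
    """
    if net is None:
        raise ValueError("net is required to locate site nodes")
    modules = partition.modules if isinstance(partition, Partition) else np.asarray(partition)
    site_modules = modules[net.n_species:]
    totals = pm.range_size().astype(float)
    if np.any(totals == 0):
        raise ValueError("species with zero presences violate the presence-matrix invariant")
    k = int(modules.max()) + 1
    counts = np.zeros((len(pm.species), k))
    coo = pm.matrix.tocoo()
    np.add.at(counts, (coo.row, site_modules[coo.col]), 1.0)
    fid = counts / totals[:, None]
    df = pd.DataFrame(fid, index=pm.species, columns=range(k))
    if assignment is not None:
        mapped = df.T.groupby(
            lambda m: assignment.module_to_region.get(int(m), 0)
        ).sum().T
        return mapped
    return df


def label_regions(assignment: RegionAssignment, env: EnvField) -> dict[int, str]:
    """Label regions 'subtrop'/'south' by the mean temperature of member
    cells relative to the global median ocean-cell temperature."""
    med = float(np.nanmedian(env.values))
    labels = {}
    for r in assignment.regions:
        cells = assignment.cells_of(r)
        mean_t = float(np.nanmean(env.values[cells.astype(int)]))
        labels[r] = "subtrop" if mean_t > med else "south"
    return labels


def to_networkx(net: BipartiteNetwork, partition: Partition | None = None) -> nx.Graph:
    g = nx.Graph()
    names = net.node_names()
    kinds = net.node_kinds()
    for i, (name, kind) in enumerate(zip(names, kinds)):
        attrs = {"kind": str(kind)}
        if partition is not None:
            attrs["module"] = int(partition.modules[i])
        g.add_node(name, **attrs)
    src = np.repeat(np.arange(net.n_nodes), np.diff(net.indptr))
    for u, v in zip(src, net.indices):
        if u < v:
            g.add_edge(names[u], names[v])
    return g


def export_network(net: BipartiteNetwork, partition: Partition | None = None, path: str = "network.gexf") -> str:
    """Write the network (with node kind and module attributes) as GEXF for
    external layout/visualization tools; losslessly re-importable."""
    nx.write_gexf(to_networkx(net, partition), path)
    return path


def import_network(path: str) -> nx.Graph:
    return nx.read_gexf(path)
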