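"""Energy-landscape structure: local minima, attractor basins, disconnectivity tree.

The 2^N activity patterns form a hypercube graph: two patterns are adjacent
iff they differ at exactly one node.  A local minimum (attractor bottom) has
energy strictly below all N neighbors.  Every state is classified to an
attractor by iterated energy descent, and the hierarchical barrier structure
among minima is summarized as a disconnectivity tree: the merge energy of two
minima is the smallest threshold E such that they are connected through
vertices of energy ≤ E (the minimax path barrier).

Exact energy ties between distinct states are broken by state index
everywhere, so all constructions are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mem import StateTable


@dataclass
class LocalMinimaSet:
    state_indices: np.ndarray  # sorted state indices of the minima
    energies: np.ndarray

    def __len__(self) -> int:
        return len(self.state_indices)


@dataclass
class BasinMap:
    """Attractor membership of every state.

    ``basin[k]`` is the state index of the local minimum reached from state
    ``k`` by steepest descent (lowest-energy strictly-smaller neighbor,
    lowest-index tie-break).  ``saddle[k]`` flags states whose steepest
    descending step is tied between neighbors that themselves descend to
    different minima; such states are still assigned deterministically.
    """

    basin: np.ndarray  # (2^N,) minimum state-index per state
    saddle: np.ndarray  # (2^N,) bool
    minima: LocalMinimaSet

    def basin_sizes(self, include_saddles: bool = True) -> dict[int, int]:
        mask = np.ones(len(self.basin), dtype=bool) if include_saddles else ~self.saddle
        idx, counts = np.unique(self.basin[mask], return_counts=True)
        sizes = {int(m): 0 for m in self.minima.state_indices}
        sizes.update({int(i): int(c) for i, c in zip(idx, counts)})
        return sizes


@dataclass
class TreeNode:
    """Node of the disconnectivity tree; leaves carry a minimum, internal nodes a merge energy."""

    energy: float
    state_index: int | None = None  # set on leaves only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.state_index is not None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class DisconnectivityTree:
    root: TreeNode
    minima: LocalMinimaSet
    # merge (minimax barrier) energy for every unordered pair of minima
    merge_energies: dict[tuple[int, int], float]

    def merge_energy(self, a: int, b: int) -> float:
        if a == b:
            i = int(np.where(self.minima.state_indices == a)[0][0])
            return float(self.minima.energies[i])
        return self.merge_energies[(min(a, b), max(a, b))]

    def basin_depths(self) -> dict[int, float]:
        """Depth of each minimum: merge level with the nearest deeper minimum
        (root level for the global minimum) minus the minimum's own energy."""
        idx = self.minima.state_indices
        E = self.minima.energies
        order = np.lexsort((idx, E))  # deepest first, index tie-break
        depths: dict[int, float] = {}
        if len(idx) == 1:
            m = int(idx[0])
            return {m: 0.0}
        root_e = self.root.energy
        for rank, oi in enumerate(order):
            m = int(idx[oi])
            if rank == 0:
                depths[m] = root_e - float(E[oi])
            else:
                deeper = [int(idx[oj]) for oj in order[:rank]]
                depths[m] = min(self.merge_energy(m, d) for d in deeper) - float(E[oi])
        return depths

    def to_newick(self, digits: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"s{node.state_index}:{node.energy:.{digits}g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.energy:.{digits}g}"

        return fmt(self.root) + ";"

    def to_dict(self) -> dict:
        def conv(node: TreeNode) -> dict:
            d: dict = {"energy": node.energy}
            if node.is_leaf:
                d["state_index"] = node.state_index
            else:
                d["children"] = [conv(c) for c in node.children]
            return d

        return conv(self.root)


def neighbor_indices(n_nodes: int) -> np.ndarray:
    """(2^N, N) matrix of Hamming-1 neighbor state indices (single-bit flips)."""
    k = np.arange(2**n_nodes, dtype=np.int64)
    return k[:, None] ^ (1 << np.arange(n_nodes, dtype=np.int64))[None, :]


def find_local_minima(table: StateTable) -> LocalMinimaSet:
    """Exhaustive scan: states with energy strictly below all N neighbors."""
    nb = neighbor_indices(table.n_nodes)
    E = table.energies
    is_min = (E[:, None] < E[nb]).all(axis=1)
    idx = np.flatnonzero(is_min)
    return LocalMinimaSet(state_indices=idx, energies=E[idx])


def _descent_target(k: int, E: np.ndarray, nb: np.ndarray) -> int:
    """Steepest-descent neighbor of state k, or -1 if k is a local minimum."""
    neighbors = nb[k]
    lower = neighbors[E[neighbors] < E[k]]
    if lower.size == 0:
        return -1
    e_min = E[lower].min()
    # lowest-index tie-break among equally steep neighbors
    return int(lower[E[lower] == e_min].min())


def assign_basins(table: StateTable, minima: LocalMinimaSet) -> BasinMap:
    """Classify every state to an attractor by iterated steepest descent.

    States are processed in increasing (energy, index) order so each state's
    steepest-descent target is already resolved.  Saddle states — ties in the
    steepest descending step between neighbors whose own descents end in
    different minima — are flagged but still assigned (via the lowest-index
    tied neighbor).
    """
    E = table.energies
    n = table.n_nodes
    nb = neighbor_indices(n)
    n_states = table.n_states

    order = np.lexsort((np.arange(n_states), E))
    basin = np.full(n_states, -1, dtype=np.int64)
    saddle = np.zeros(n_states, dtype=bool)
    min_set = set(int(m) for m in minima.state_indices)

    for k in order:
        k = int(k)
        target = _descent_target(k, E, nb)
        if target < 0:
            if k not in min_set:
                raise RuntimeError(f"state {k} has no descent but is not a listed minimum")
            basin[k] = k
            continue
        basin[k] = basin[target]
        neighbors = nb[k]
        lower = neighbors[E[neighbors] < E[k]]
        tied = lower[E[lower] == E[lower].min()]
        if len(tied) > 1 and len(set(int(basin[t]) for t in tied)) > 1:
            saddle[k] = True

    return BasinMap(basin=basin, saddle=saddle, minima=minima)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra


def build_disconnectivity(table: StateTable, minima: LocalMinimaSet) -> DisconnectivityTree:
    """Disconnectivity tree by the threshold-lowering construction.

    Equivalently (and as implemented): insert vertices in increasing
    (energy, index) order, connecting each to already-inserted neighbors;
    when two components that contain minima first touch, the energy of the
    inserting vertex is the merge (minimax barrier) energy of every pair of
    minima across the two components.  A single minimum yields a one-leaf
    tree.
    """
    E = table.energies
    nb = neighbor_indices(table.n_nodes)
    n_states = table.n_states
    order = np.lexsort((np.arange(n_states), E))

    uf = _UnionFind(n_states)
    inserted = np.zeros(n_states, dtype=bool)
    # per-component bookkeeping, keyed by union-find root
    comp_minima: dict[int, list[int]] = {}
    comp_tree: dict[int, TreeNode] = {}
    merge_energies: dict[tuple[int, int], float] = {}
    min_set = set(int(m) for m in minima.state_indices)

    for k in order:
        k = int(k)
        inserted[k] = True
        root = uf.find(k)
        if k in min_set:
            leaf = TreeNode(energy=float(E[k]), state_index=k)
            comp_minima[root] = [k]
            comp_tree[root] = leaf
        for j in nb[k]:
            j = int(j)
            if not inserted[j]:
                continue
            ra, rb = uf.find(k), uf.find(j)
            if ra == rb:
                continue
            ma = comp_minima.pop(ra, [])
            mb = comp_minima.pop(rb, [])
            ta = comp_tree.pop(ra, None)
            tb = comp_tree.pop(rb, None)
            if ma and mb:
                for a in ma:
                    for b in mb:
                        merge_energies[(min(a, b), max(a, b))] = float(E[k])
            new_root = uf.union(ra, rb)
            merged = ma + mb
            if ta is not None and tb is not None:
                comp_tree[new_root] = TreeNode(energy=float(E[k]), children=[ta, tb])
            elif ta is not None or tb is not None:
                comp_tree[new_root] = ta if ta is not None else tb
            if merged:
                comp_minima[new_root] = merged

    if len(comp_tree) != 1:
        raise RuntimeError("hypercube insertion did not end in a single component")
    root_tree = next(iter(comp_tree.values()))
    return DisconnectivityTree(root=root_tree, minima=minima, merge_energies=merge_energies)
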