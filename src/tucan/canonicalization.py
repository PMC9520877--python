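"""Canonical node labeling from topology and atomic numbers only.

The pipeline has three stages:

1. **Invariant codes** — every node gets the code ``(Z, multiset of
   neighbor Z values sorted decreasing)``.  The atomic number is the only
   chemistry-specific invariant; bond orders, charges, isotopes and
   radicals play no role here.
2. **Initial partitioning + Weisfeiler-Lehman refinement** — nodes with
   identical codes share a cell; cells are then split iteratively by the
   multiset of neighbor cell indices (1-D WL, the Morgan algorithm) until
   the partition is equitable.
3. **Individualization-refinement** — remaining symmetry is broken by
   provisionally singling out each member of the first non-singleton cell,
   re-refining, and keeping the branch whose discrete labeling minimizes
   the canonical form key (sorted edge list, then node-feature list, under
   the induced output labels).  The result is invariant under any
   permutation of the input atom order.

The ordered partition keeps cells sorted so that positions are grouped by
ascending atomic number; within one element, cells compare by their
neighbor multiset elementwise ascending, with a prefix tie broken toward
the longer multiset (higher-degree environments first).  This makes the
search minimum coincide with the brute-force lexicographic minimum over
element-respecting labelings on small graphs, which is how the stage is
validated.

Node features (CHG/MASS/RAD) enter only as the *final* tie-break of the
leaf key, after the edge list: they cannot change which topological
labelings are candidates, but they make the serialized string
deterministic for molecules whose features sit on symmetry-equivalent
atoms (e.g. singly deuterated water).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import networkx as nx

#: Sentinel appended to neighbor multisets when ordering cells: larger than
#: any atomic number, so a multiset that is a strict prefix of another
#: sorts *after* it (shorter = lower degree = later).
_SENTINEL = 1 << 20

InvariantCode = tuple[int, tuple[int, ...]]


def assign_invariant_codes(graph: nx.Graph) -> dict[int, InvariantCode]:
    """Per-node code: atomic number + decreasing multiset of neighbor Zs."""
    codes = {}
    for v in graph.nodes:
        z = graph.nodes[v]["atomic_number"]
        neighbors = tuple(
            sorted((graph.nodes[u]["atomic_number"] for u in graph[v]), reverse=True)
        )
        codes[v] = (z, neighbors)
    return codes


@dataclass(frozen=True)
class Partitioning:
    """An ordered partition of the node set into cells 0..k-1."""

    cells: tuple[tuple[int, ...], ...]

    @property
    def assignment(self) -> dict[int, int]:
        """Map node label -> partition index."""
        return {v: i for i, cell in enumerate(self.cells) for v in cell}

    def __len__(self) -> int:
        return len(self.cells)

    def is_discrete(self) -> bool:
        return all(len(cell) == 1 for cell in self.cells)


def _cell_order_key(code: InvariantCode) -> tuple:
    z, neighbors = code
    return (z, neighbors + (_SENTINEL,))


def initial_partition(codes: dict[int, InvariantCode]) -> Partitioning:
    """Group nodes with identical invariant codes into ordered cells."""
    groups: dict[InvariantCode, list[int]] = {}
    for v, code in codes.items():
        groups.setdefault(code, []).append(v)
    cells = tuple(
        tuple(sorted(groups[code])) for code in sorted(groups, key=_cell_order_key)
    )
    return Partitioning(cells)


def _graph_arrays(graph: nx.Graph):
    n = graph.number_of_nodes()
    if sorted(graph.nodes) != list(range(n)):
        raise ValueError("node labels must be contiguous 0..n-1")
    adj = [sorted(graph[v]) for v in range(n)]
    feats = [
        tuple(sorted(graph.nodes[v].get("features", {}).items())) for v in range(n)
    ]
    return n, adj, feats


def _refine(adj, cells):
    """Iterate the 1-D WL step until the ordered partition is equitable.

    Every cell is split by the multiset of neighbor cell indices; subcells
    replace their parent in place, ordered by ascending key, so the overall
    cell order stays content-based.  Cells are never merged.
    """
    n = sum(len(c) for c in cells)
    cell_of = [0] * n
    for i, cell in enumerate(cells):
        for v in cell:
            cell_of[v] = i
    while True:
        new_cells = []
        changed = False
        for cell in cells:
            if len(cell) == 1:
                new_cells.append(cell)
                continue
            groups: dict[tuple[int, ...], list[int]] = {}
            for v in cell:
                key = tuple(sorted(cell_of[u] for u in adj[v]))
                groups.setdefault(key, []).append(v)
            if len(groups) == 1:
                new_cells.append(cell)
            else:
                changed = True
                for key in sorted(groups):
                    new_cells.append(groups[key])
        if not changed:
            return cells
        cells = new_cells
        for i, cell in enumerate(cells):
            for v in cell:
                cell_of[v] = i


def refine_partitions(graph: nx.Graph, p: Partitioning) -> Partitioning:
    """Refine a partitioning to its stable (equitable) form."""
    _, adj, _ = _graph_arrays(graph)
    cells = _refine(adj, [list(c) for c in p.cells])
    return Partitioning(tuple(tuple(c) for c in cells))


def refinement_rounds(graph: nx.Graph, p: Partitioning):
    """Yield the partitioning after each WL round, until stable.

    One round recomputes every cell's split; the generator stops after the
    first round that changes nothing (which is not yielded).  Used by the
    CLI ``trace`` command.
    """
    _, adj, _ = _graph_arrays(graph)
    cells = [list(c) for c in p.cells]
    n = sum(len(c) for c in cells)
    while True:
        cell_of = [0] * n
        for i, cell in enumerate(cells):
            for v in cell:
                cell_of[v] = i
        new_cells = []
        changed = False
        for cell in cells:
            groups: dict[tuple[int, ...], list[int]] = {}
            for v in cell:
                key = tuple(sorted(cell_of[u] for u in adj[v]))
                groups.setdefault(key, []).append(v)
            if len(groups) == 1:
                new_cells.append(cell)
            else:
                changed = True
                for key in sorted(groups):
                    new_cells.append(groups[key])
        if not changed:
            return
        cells = new_cells
        yield Partitioning(tuple(tuple(c) for c in cells))


def _leaf_key(n, adj, feats, pos):
    """Canonical form key of a discrete labeling: (edge list, features).

    ``pos[v]`` is v's 0-based canonical position; tuples are compared
    numerically, and positions are emitted 1-based to mirror the string.
    """
    edges = []
    for v in range(n):
        pv = pos[v]
        for u in adj[v]:
            if u > v:
                pu = pos[u]
                edges.append((pv, pu) if pv < pu else (pu, pv))
    edges.sort()
    features = sorted((pos[v], feats[v]) for v in range(n) if feats[v])
    return (
        tuple((a + 1, b + 1) for a, b in edges),
        tuple((p + 1, f) for p, f in features),
    )


class _PruneTo(Exception):
    """Backtrack signal: the current subtree is automorphic to an explored one."""

    def __init__(self, depth: int):
        self.depth = depth


def _search(n, adj, feats, cells):
    """Explore the individualization-refinement tree, return the best leaf.

    The minimum leaf key over the whole tree is the canonical form.  When a
    leaf reproduces the current best key *and* places the individualized
    base vertices at the same positions, the two paths are related by an
    automorphism; the search then abandons the subtree rooted at the first
    base divergence, which prunes symmetric graphs from factorial to
    roughly automorphism-group size without affecting the minimum.
    """
    best: dict | None = None

    def recurse(cells, base):
        nonlocal best
        cells = _refine(adj, cells)
        target = next((i for i, c in enumerate(cells) if len(c) > 1), None)
        if target is None:
            pos = [0] * n
            for i, cell in enumerate(cells):
                pos[cell[0]] = i
            key = _leaf_key(n, adj, feats, pos)
            if best is None or key < best["key"]:
                best = {
                    "key": key,
                    "pos": pos,
                    "base": list(base),
                    "base_pos": [pos[v] for v in base],
                }
            elif key == best["key"] and len(base) == len(best["base"]):
                if [pos[v] for v in base] == best["base_pos"]:
                    diverge = next(
                        (
                            i
                            for i in range(len(base))
                            if base[i] != best["base"][i]
                        ),
                        None,
                    )
                    if diverge is not None:
                        raise _PruneTo(diverge)
            return
        head = cells[:target]
        rest = cells[target + 1 :]
        depth = len(base)
        for w in cells[target]:
            child = head + [[w], [x for x in cells[target] if x != w]] + rest
            base.append(w)
            try:
                recurse(child, base)
            except _PruneTo as prune:
                if prune.depth < depth:
                    base.pop()
                    raise
                # automorphic to an already-explored sibling: next member
            base.pop()

    recurse([list(c) for c in cells], [])
    assert best is not None
    return best


def canonical_labeling(
    graph: nx.Graph, stable: Partitioning | None = None
) -> dict[int, int]:
    """Compute the canonical labeling (bijection node -> 0..n-1).

    If ``stable`` is not given, the invariant-code partition is computed
    and refined first.  The returned labeling is invariant under any input
    permutation of the same graph: relabeling the input permutes the
    mapping's keys but serializes to the identical string.
    """
    if stable is None:
        stable = refine_partitions(graph, initial_partition(assign_invariant_codes(graph)))
    n, adj, feats = _graph_arrays(graph)
    best = _search(n, adj, feats, stable.cells)
    return {v: best["pos"][v] for v in range(n)}


def canonical_form_key(graph: nx.Graph, labeling: dict[int, int] | None = None):
    """The (edge list, feature list) key of a graph under a labeling."""
    if labeling is None:
        labeling = canonical_labeling(graph)
    n, adj, feats = _graph_arrays(graph)
    pos = [0] * n
    for v, p in labeling.items():
        pos[v] = p
    return _leaf_key(n, adj, feats, pos)


def brute_force_canonical(graph: nx.Graph, max_atoms: int = 8):
    """Test oracle: minimum form key over all element-respecting labelings.

    Enumerates every assignment of canonical positions in which positions
    increase with atomic number (the serialization's labeling rule) and
    returns the lexicographically minimal key.  Factorial cost, so graphs
    above ``max_atoms`` are refused.
    """
    n, adj, feats = _graph_arrays(graph)
    if n > max_atoms:
        raise ValueError(f"brute force refused for n={n} > {max_atoms}")
    by_z: dict[int, list[int]] = {}
    for v in range(n):
        by_z.setdefault(graph.nodes[v]["atomic_number"], []).append(v)
    blocks = [by_z[z] for z in sorted(by_z)]
    starts = []
    offset = 0
    for block in blocks:
        starts.append(offset)
        offset += len(block)
    best = None
    for orderings in product(*(permutations(block) for block in blocks)):
        pos = [0] * n
        for start, ordering in zip(starts, orderings):
            for i, v in enumerate(ordering):
                pos[v] = start + i
        key = _leaf_key(n, adj, feats, pos)
        if best is None or key < best:
            best = key
    return best
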