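"""The internal molecular-graph model.

A molecule is an undirected labeled graph without multi-edges or loops:
atoms are nodes, bonds are edges.  The container is a plain
:class:`networkx.Graph` whose nodes are contiguous 0-based integers
carrying these attributes:

``element_symbol``, ``atomic_number``
    the only chemistry-specific data used by the canonicalization;
``partition``
    mutable refinement state, initialized to 0 for every node;
``features``
    dict of explicitly present CHG/MASS/RAD fields (serialized, but not
    part of the canonicalization invariants);
anything else
    custom display-only attributes (e.g. element colors); these never
    influence canonicalization, which is enforced by test.

Edges carry no attributes.  Disconnected graphs are legal: the identifier
covers monoatomic species and ion pairs whose atoms share no bond.
"""

from __future__ import annotations

import networkx as nx

from .elements import element_to_atomic_number
from .molfile import MolfileData

#: Node attributes that define structural identity.  ``partition`` is
#: transient refinement state and custom attributes are display-only, so
#: neither participates in equality.
_IDENTITY_ATTRS = ("element_symbol", "atomic_number", "features")

MolecularGraph = nx.Graph


def build_graph(data: MolfileData) -> nx.Graph:
    """Build the molecular graph for parsed molfile data.

    Node ``i`` (0-based) corresponds to ATOM record ``i + 1``; every bond
    becomes one undirected edge; all partitions start at 0.
    """
    graph = nx.Graph()
    for atom in data.atoms:
        graph.add_node(
            atom.index - 1,
            element_symbol=atom.element_symbol,
            atomic_number=atom.atomic_number,
            partition=0,
            features=atom.features(),
        )
    for bond in data.bonds:
        graph.add_edge(bond.atom_a - 1, bond.atom_b - 1)
    return graph


def graph_from_atoms(
    elements: list[str],
    edges: list[tuple[int, int]],
    features: dict[int, dict[str, int]] | None = None,
) -> nx.Graph:
    """Convenience constructor from element symbols and 0-based edges."""
    graph = nx.Graph()
    for label, symbol in enumerate(elements):
        graph.add_node(
            label,
            element_symbol=symbol,
            atomic_number=element_to_atomic_number(symbol),
            partition=0,
            features=dict((features or {}).get(label, {})),
        )
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-bond on atom {a}")
        graph.add_edge(a, b)
    return graph


def neighbor_atomic_numbers(graph: nx.Graph, label: int) -> tuple[int, ...]:
    """Atomic numbers of all neighbors, with multiplicity, decreasing."""
    if label not in graph:
        raise KeyError(f"no node with label {label}")
    return tuple(
        sorted(
            (graph.nodes[nbr]["atomic_number"] for nbr in graph[label]),
            reverse=True,
        )
    )


def relabel(graph: nx.Graph, mapping: dict[int, int]) -> nx.Graph:
    """Return a copy of the graph with nodes renamed by a bijection.

    The mapping must be a bijection over the existing labels onto
    ``0..n-1``; all node attributes travel with their node.
    """
    n = graph.number_of_nodes()
    if set(mapping) != set(graph.nodes) or set(mapping.values()) != set(range(n)):
        raise ValueError("mapping is not a bijection over the node labels")
    return nx.relabel_nodes(graph, mapping, copy=True)


def graph_equal(a: nx.Graph, b: nx.Graph) -> bool:
    """Structural equality: same labels, identity attributes and edge set."""
    if set(a.nodes) != set(b.nodes):
        return False
    for label in a.nodes:
        for attr in _IDENTITY_ATTRS:
            if a.nodes[label].get(attr) != b.nodes[label].get(attr):
                return False
    normalize = lambda g: {(min(u, v), max(u, v)) for u, v in g.edges}
    return normalize(a) == normalize(b)
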