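"""Serialization of a canonically labeled graph into the identifier string.

The string has up to three slash-separated blocks::

    formula / edge-tuple list / node-feature list

* The **formula** is the Hill sum formula (C first, then H, then the
  remaining elements alphabetically; with no carbon present, everything
  alphabetical).  It is the only mandatory block: monoatomic species and
  fully disconnected compounds serialize as the formula alone.
* The **edge list** holds one ``(a-b)`` tuple per bond, ``a < b``, sorted
  by ``(a, b)``.  Output labels are 1-based and increase with atomic
  number, so which label is which element is inferable from the formula.
* The **feature list** holds one ``(label:FIELD=VALUE,...)`` entry per
  atom with explicit CHG/MASS/RAD fields, fields sorted by name, entries
  sorted by label, no whitespace.

All characters are plain printable ASCII ("-" hyphen, "=" equals).
"""

from __future__ import annotations

import networkx as nx

from .canonicalization import canonical_labeling
from .molfile import FEATURE_FIELDS

HillFormula = list[tuple[str, int]]


def hill_formula(graph: nx.Graph) -> HillFormula:
    """Element counts in Hill order; permutation-invariant."""
    counts: dict[str, int] = {}
    for v in graph.nodes:
        symbol = graph.nodes[v]["element_symbol"]
        counts[symbol] = counts.get(symbol, 0) + 1
    ordered: list[str] = []
    if "C" in counts:
        ordered.append("C")
        if "H" in counts:
            ordered.append("H")
        ordered.extend(s for s in sorted(counts) if s not in ("C", "H"))
    else:
        ordered.extend(sorted(counts))
    return [(s, counts[s]) for s in ordered]


def format_hill_formula(formula: HillFormula) -> str:
    """Render the formula; a count of 1 omits the digit (``Pt``, not ``Pt1``)."""
    return "".join(s if c == 1 else f"{s}{c}" for s, c in formula)


def assign_output_labels(
    graph: nx.Graph, canon: dict[int, int]
) -> dict[int, int]:
    """Map every node to its 1-based output label.

    Atoms are ordered by ascending atomic number first and ascending
    canonical label second, so increasing labels go with increasing atomic
    number (in Zeise's anion: H 1-4, C 5-6, Cl 7-9, Pt 10).
    """
    order = sorted(
        graph.nodes, key=lambda v: (graph.nodes[v]["atomic_number"], canon[v])
    )
    return {v: i for i, v in enumerate(order, start=1)}


def serialize(graph: nx.Graph, canon: dict[int, int] | None = None) -> str:
    """Serialize a molecular graph to its identifier string.

    Computes the canonical labeling if one is not supplied.  Empty edge
    and feature blocks are omitted.
    """
    if canon is None:
        canon = canonical_labeling(graph)
    labels = assign_output_labels(graph, canon)

    blocks = [format_hill_formula(hill_formula(graph))]
    edges = sorted(
        (min(labels[u], labels[v]), max(labels[u], labels[v]))
        for u, v in graph.edges
    )
    if edges:
        blocks.append("".join(f"({a}-{b})" for a, b in edges))
    features = []
    for v in graph.nodes:
        present = graph.nodes[v].get("features", {})
        if present:
            fields = ",".join(f"{k}={present[k]}" for k in FEATURE_FIELDS if k in present)
            features.append((labels[v], fields))
    if features:
        blocks.append("".join(f"({label}:{fields})" for label, fields in sorted(features)))
    return "/".join(blocks)
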