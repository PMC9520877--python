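"""Parsing identifier strings back into molecular graphs.

The string is a descriptor, not just an identifier: formula + edge list +
feature list determine the labeled graph completely, so a coordinate-free
molfile can be reconstructed from it.

Label-to-element resolution expands the Hill formula by **ascending atomic
number** — label 1 is the lightest element's first atom — which is the
serializer's labeling rule and deliberately differs from the formula's
print order (Zeise's formula starts with C, but labels 1-4 are H).

Grammatical but non-canonical strings (labels permuted within an element)
are accepted and simply re-canonicalize on round trip; ``strict`` mode
rejects any string whose re-serialization differs from the input.  A
fourth, custom-data block is preserved verbatim and otherwise ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

from .elements import UnknownElementError, element_to_atomic_number
from .graphs import graph_from_atoms
from .molfile import FEATURE_FIELDS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]{0,2})(\d*)")
_EDGE_TUPLE = re.compile(r"\((\d+)-(\d+)\)")
_FEATURE_ENTRY = re.compile(r"\((\d+):([A-Z]+=-?\d+(?:,[A-Z]+=-?\d+)*)\)")


class TucanParseError(ValueError):
    """Raised for strings that violate the identifier grammar."""


@dataclass
class ParsedTucan:
    """Structured form of one parsed identifier string."""

    formula: list[tuple[str, int]]
    edges: list[tuple[int, int]] = field(default_factory=list)
    features: dict[int, dict[str, int]] = field(default_factory=dict)
    custom: str | None = None

    @property
    def atom_count(self) -> int:
        return sum(count for _, count in self.formula)


def _parse_formula(block: str) -> list[tuple[str, int]]:
    if not block:
        raise TucanParseError("empty formula block")
    formula: list[tuple[str, int]] = []
    seen: set[str] = set()
    position = 0
    while position < len(block):
        match = _FORMULA_TOKEN.match(block, position)
        if match is None or not match.group(1):
            raise TucanParseError(
                f"malformed formula at {block[position:]!r}"
            )
        symbol, digits = match.group(1), match.group(2)
        try:
            element_to_atomic_number(symbol)
        except UnknownElementError as exc:
            raise TucanParseError(str(exc)) from None
        count = int(digits) if digits else 1
        if count < 1:
            raise TucanParseError(f"element {symbol} with count {count}")
        if symbol in seen:
            raise TucanParseError(f"element {symbol} appears twice in formula")
        seen.add(symbol)
        formula.append((symbol, count))
        position = match.end()
    return formula


def _parse_block(pattern: re.Pattern, block: str, what: str):
    matches = list(pattern.finditer(block))
    covered = "".join(m.group(0) for m in matches)
    if covered != block:
        raise TucanParseError(f"malformed {what} block: {block!r}")
    return matches


def _parse_edges(block: str, atom_count: int) -> list[tuple[int, int]]:
    edges: list[tuple[int, int]] = []
    for match in _parse_block(_EDGE_TUPLE, block, "edge"):
        a, b = int(match.group(1)), int(match.group(2))
        if a >= b:
            raise TucanParseError(
                f"edge tuple ({a}-{b}) not in ascending order"
            )
        if b > atom_count:
            raise TucanParseError(
                f"edge tuple ({a}-{b}) references label {b} > {atom_count}"
            )
        if a < 1:
            raise TucanParseError(f"edge tuple ({a}-{b}) references label {a} < 1")
        if edges and (a, b) <= edges[-1]:
            if (a, b) == edges[-1]:
                raise TucanParseError(f"duplicate edge ({a}-{b})")
            raise TucanParseError(
                f"edge list not sorted at ({a}-{b})"
            )
        edges.append((a, b))
    return edges


def _parse_features(block: str, atom_count: int) -> dict[int, dict[str, int]]:
    features: dict[int, dict[str, int]] = {}
    last_label = 0
    for match in _parse_block(_FEATURE_ENTRY, block, "feature"):
        label = int(match.group(1))
        if not 1 <= label <= atom_count:
            raise TucanParseError(f"feature label {label} outside 1..{atom_count}")
        if label <= last_label:
            raise TucanParseError(
                f"feature entries not sorted by increasing label at {label}"
            )
        last_label = label
        fields: dict[str, int] = {}
        for item in match.group(2).split(","):
            name, _, value = item.partition("=")
            if name not in FEATURE_FIELDS:
                raise TucanParseError(f"unknown FIELD name {name!r}")
            if name in fields:
                raise TucanParseError(f"FIELD {name} repeated for label {label}")
            fields[name] = int(value)
        if list(fields) != sorted(fields):
            raise TucanParseError(
                f"FIELDs for label {label} not sorted lexicographically"
            )
        features[label] = fields
    return features


def parse_tucan_string(s: str) -> ParsedTucan:
    """Parse an identifier string into its structured form.

    Validation is strict about the grammar: sorted ascending edge tuples,
    sorted feature entries and field names, labels within the atom count
    implied by the formula, known FIELD names.
    """
    if not s or s != s.strip():
        raise TucanParseError("empty string or leading/trailing whitespace")
    parts = s.split("/")
    parsed = ParsedTucan(formula=_parse_formula(parts[0]))
    index = 1
    if index < len(parts) and ":" not in parts[index] and parts[index]:
        parsed.edges = _parse_edges(parts[index], parsed.atom_count)
        index += 1
    if index < len(parts) and ":" in parts[index]:
        parsed.features = _parse_features(parts[index], parsed.atom_count)
        index += 1
    if index < len(parts):
        parsed.custom = parts[index]
        index += 1
    if index < len(parts):
        raise TucanParseError(f"too many '/'-separated blocks ({len(parts)})")
    if parsed.custom == "":
        raise TucanParseError("empty block")
    return parsed


def to_graph(parsed: ParsedTucan) -> nx.Graph:
    """Build the molecular graph a parsed string describes.

    Node ``i`` (0-based) mirrors label ``i + 1``; element symbols come
    from expanding the formula by ascending atomic number.
    """
    expansion: list[str] = []
    for symbol, count in sorted(
        parsed.formula, key=lambda item: element_to_atomic_number(item[0])
    ):
        expansion.extend([symbol] * count)
    edges = [(a - 1, b - 1) for a, b in parsed.edges]
    features = {label - 1: dict(fields) for label, fields in parsed.features.items()}
    return graph_from_atoms(expansion, edges, features)


def graph_from_tucan(s: str, strict: bool = False) -> nx.Graph:
    """Parse a string to a graph; ``strict`` requires it to be canonical."""
    graph = to_graph(parse_tucan_string(s))
    if strict:
        from .serialization import serialize

        canonical = serialize(graph)
        if canonical != s:
            raise TucanParseError(
                f"string is not canonical: re-serializes to {canonical!r}"
            )
    return graph
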