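"""Reading and writing the molfile v3000 subset consumed by TUCAN.

Only three sets of values are retained from a v3000 connection table: the
atom/bond counts, the element symbol of every atom together with its optional
``CHG`` (formal charge), ``MASS`` (isotope mass number) and ``RAD``
(radical/multiplicity code) keywords, and the bond pair list.  Coordinates,
bond types and every other field are discarded: connectivity and atomic
number are the only inputs the canonicalization uses.

Hydrogens are handled explicitly: atoms not present in the file do not
exist as far as the identifier is concerned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .elements import element_to_atomic_number

#: Keywords of the ATOM-block fields that are carried through to the
#: identifier's node-feature block, in their serialization sort order.
FEATURE_FIELDS = ("CHG", "MASS", "RAD")


class MolfileParseError(ValueError):
    """Raised for structurally invalid or unsupported molfile input."""


@dataclass(frozen=True)
class AtomRecord:
    """One parsed ATOM-block entry.

    ``charge``/``mass``/``radical`` are ``None`` when the keyword is absent
    from the file.  Presence is meaningful even at the default value: an
    explicit ``RAD=0`` is preserved and serialized (Zeise's Pt carries one),
    an absent ``RAD`` is not invented.
    """

    index: int  # 1-based position in the ATOM block
    element_symbol: str
    charge: int | None = None
    mass: int | None = None
    radical: int | None = None

    @property
    def atomic_number(self) -> int:
        return element_to_atomic_number(self.element_symbol)

    def features(self) -> dict[str, int]:
        """The explicitly present CHG/MASS/RAD fields as a dict."""
        out = {}
        if self.charge is not None:
            out["CHG"] = self.charge
        if self.mass is not None:
            out["MASS"] = self.mass
        if self.radical is not None:
            out["RAD"] = self.radical
        return out


@dataclass(frozen=True)
class BondRecord:
    """An undirected bond as a pair of 1-based atom indices."""

    atom_a: int
    atom_b: int


@dataclass
class MolfileData:
    """The retained content of one molfile v3000 record."""

    atom_count: int
    bond_count: int
    atoms: list[AtomRecord] = field(default_factory=list)
    bonds: list[BondRecord] = field(default_factory=list)


def _logical_lines(text: str) -> list[str]:
    """Extract ``M  V30`` payload lines, joining ``-`` continuations."""
    lines = []
    pending = None
    for raw in text.splitlines():
        stripped = raw.strip()
        if not stripped.startswith("M  V30"):
            if pending is not None:
                raise MolfileParseError(
                    "line continuation not followed by an 'M  V30' line"
                )
            continue
        payload = stripped[6:].strip()
        if pending is not None:
            payload = pending + payload
            pending = None
        if payload.endswith("-"):
            pending = payload[:-1]
            continue
        lines.append(payload)
    if pending is not None:
        raise MolfileParseError("molfile ends inside a line continuation")
    return lines


def _parse_keyword_fields(tokens: list[str], index: int) -> dict[str, int]:
    fields: dict[str, int] = {}
    for token in tokens:
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        if key not in FEATURE_FIELDS:
            continue  # other keywords (e.g. VAL, ATTCHPT) are discarded
        try:
            fields[key] = int(value)
        except ValueError:
            raise MolfileParseError(
                f"atom {index}: non-integer value {value!r} for {key}"
            ) from None
    if not 0 <= fields.get("RAD", 0) <= 3:
        raise MolfileParseError(
            f"atom {index}: RAD={fields['RAD']} outside the valid range 0-3"
        )
    return fields


def parse_molfile_v3000(text: str) -> MolfileData:
    """Parse a molfile v3000 document into :class:`MolfileData`.

    The file is otherwise assumed chemically valid; only elemental checks
    are performed.  Fatal conditions: missing/contradictory counts, element
    symbols outside H..Og (including the ``*`` pseudo-atom), bond indices
    out of range, self-bonds and duplicate bonds.
    """
    if "V3000" not in text and "V30" not in text:
        raise MolfileParseError("not a molfile v3000 document (no 'V30' lines)")
    lines = _logical_lines(text)
    if not any(line.startswith("BEGIN CTAB") for line in lines):
        raise MolfileParseError("missing 'M  V30 BEGIN CTAB'")

    counts: tuple[int, int] | None = None
    atoms: list[AtomRecord] = []
    bonds: list[BondRecord] = []
    block: str | None = None
    for line in lines:
        tokens = line.split()
        if not tokens:
            continue
        if tokens[0] == "BEGIN":
            block = tokens[1] if len(tokens) > 1 else None
            continue
        if tokens[0] == "END":
            block = None
            continue
        if tokens[0] == "COUNTS":
            try:
                counts = (int(tokens[1]), int(tokens[2]))
            except (IndexError, ValueError):
                raise MolfileParseError(f"malformed COUNTS line: {line!r}") from None
            continue
        if block == "ATOM":
            atoms.append(_parse_atom_line(tokens, line))
        elif block == "BOND":
            bonds.append(_parse_bond_line(tokens, line))
        # all other blocks (SGROUP, COLLECTION, ...) are ignored

    if counts is None:
        raise MolfileParseError("missing 'M  V30 COUNTS' line")
    atom_count, bond_count = counts
    if atom_count < 1:
        raise MolfileParseError(f"atom count must be >= 1, got {atom_count}")
    if len(atoms) != atom_count:
        raise MolfileParseError(
            f"COUNTS declares {atom_count} atoms but ATOM block has {len(atoms)}"
        )
    if len(bonds) != bond_count:
        raise MolfileParseError(
            f"COUNTS declares {bond_count} bonds but BOND block has {len(bonds)}"
        )
    expected = list(range(1, atom_count + 1))
    if [a.index for a in atoms] != expected:
        raise MolfileParseError("ATOM block indices are not 1..n in order")
    _validate_bonds(bonds, atom_count)
    return MolfileData(atom_count, bond_count, atoms, bonds)


def _parse_atom_line(tokens: list[str], line: str) -> AtomRecord:
    # M  V30 index type x y z aamap [KEY=VALUE ...]
    if len(tokens) < 2:
        raise MolfileParseError(f"malformed ATOM line: {line!r}")
    try:
        index = int(tokens[0])
    except ValueError:
        raise MolfileParseError(f"non-integer atom index in: {line!r}") from None
    symbol = tokens[1]
    element_to_atomic_number(symbol)  # raises UnknownElementError if invalid
    fields = _parse_keyword_fields(tokens[2:], index)
    return AtomRecord(
        index=index,
        element_symbol=symbol,
        charge=fields.get("CHG"),
        mass=fields.get("MASS"),
        radical=fields.get("RAD"),
    )


def _parse_bond_line(tokens: list[str], line: str) -> BondRecord:
    # M  V30 index type atom1 atom2 [...] -- the bond type is discarded
    if len(tokens) < 4:
        raise MolfileParseError(f"malformed BOND line: {line!r}")
    try:
        atom_a, atom_b = int(tokens[2]), int(tokens[3])
    except ValueError:
        raise MolfileParseError(f"non-integer bond endpoint in: {line!r}") from None
    return BondRecord(atom_a, atom_b)


def _validate_bonds(bonds: list[BondRecord], atom_count: int) -> None:
    seen: set[tuple[int, int]] = set()
    for bond in bonds:
        if bond.atom_a == bond.atom_b:
            raise MolfileParseError(f"self-bond on atom {bond.atom_a}")
        for endpoint in (bond.atom_a, bond.atom_b):
            if not 1 <= endpoint <= atom_count:
                raise MolfileParseError(
                    f"bond endpoint {endpoint} outside 1..{atom_count}"
                )
        key = (min(bond.atom_a, bond.atom_b), max(bond.atom_a, bond.atom_b))
        if key in seen:
            raise MolfileParseError(f"duplicate bond {key[0]}-{key[1]}")
        seen.add(key)


def write_molfile_v3000(graph) -> str:
    """Write a coordinate-free molfile v3000 for a molecular graph.

    Atoms are emitted in node-label order with zeroed coordinates; every
    bond is written as type 1 (single), since bond orders are not part of
    the representation.  CHG/MASS/RAD are emitted exactly when present in
    the node's feature dict.  The output parses back to the same atoms,
    features and edge set.
    """
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    lines = [
        "",
        "  TUCAN",
        "",
        f"  0  0  0     0  0            999 V3000",
        "M  V30 BEGIN CTAB",
        f"M  V30 COUNTS {n} {m} 0 0 0",
        "M  V30 BEGIN ATOM",
    ]
    for label in sorted(graph.nodes):
        data = graph.nodes[label]
        entry = f"M  V30 {label + 1} {data['element_symbol']} 0.0 0.0 0.0 0"
        features = data.get("features", {})
        for key in FEATURE_FIELDS:
            if key in features:
                entry += f" {key}={features[key]}"
        lines.append(entry)
    lines.append("M  V30 END ATOM")
    lines.append("M  V30 BEGIN BOND")
    for i, (a, b) in enumerate(
        sorted((min(a, b), max(a, b)) for a, b in graph.edges), start=1
    ):
        lines.append(f"M  V30 {i} 1 {a + 1} {b + 1}")
    lines.append("M  V30 END BOND")
    lines.append("M  V30 END CTAB")
    lines.append("M  END")
    return "\n".join(lines) + "\n"
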