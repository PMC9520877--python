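"""TUCAN: a canonical, bidirectional tuple-style molecular identifier.

The identifier applies to any molecule over elements 1 (H) through
118 (Og): canonicalization uses only the molecular topology and atomic
numbers — no bond orders, valences or other domain-specific bonding
concepts — so organometallic, coordination and cluster compounds are
first-class citizens.  Strings look like::

    C2H4Cl3Pt/(1-5)(2-5)(3-6)(4-6)(5-6)(5-10)(6-10)(7-10)(8-10)(9-10)/
    (7:CHG=-1)(8:CHG=-1)(9:CHG=-1)(10:CHG=2,MASS=196,RAD=0)

(Zeise's anion) and can be converted back to a molecular graph or a
coordinate-free molfile without loss.
"""

from .canonicalization import (
    Partitioning,
    assign_invariant_codes,
    brute_force_canonical,
    canonical_form_key,
    canonical_labeling,
    initial_partition,
    refine_partitions,
)
from .deserialization import (
    ParsedTucan,
    TucanParseError,
    graph_from_tucan,
    parse_tucan_string,
    to_graph,
)
from .elements import UnknownElementError, element_to_atomic_number
from .graphs import (
    MolecularGraph,
    build_graph,
    graph_from_atoms,
    neighbor_atomic_numbers,
    relabel,
)
from .molfile import (
    AtomRecord,
    BondRecord,
    MolfileData,
    MolfileParseError,
    parse_molfile_v3000,
    write_molfile_v3000,
)
from .serialization import assign_output_labels, hill_formula, serialize

__version__ = "0.1.0"


def tucan_from_molfile(text: str) -> str:
    """Molfile v3000 document -> canonical identifier string."""
    graph = build_graph(parse_molfile_v3000(text))
    return serialize(graph, canonical_labeling(graph))


def molfile_from_tucan(s: str, strict: bool = False) -> str:
    """Identifier string -> reconstructed coordinate-free molfile v3000."""
    return write_molfile_v3000(graph_from_tucan(s, strict=strict))


__all__ = [
    "AtomRecord",
    "BondRecord",
    "MolecularGraph",
    "MolfileData",
    "MolfileParseError",
    "ParsedTucan",
    "Partitioning",
    "TucanParseError",
    "UnknownElementError",
    "assign_invariant_codes",
    "assign_output_labels",
    "brute_force_canonical",
    "build_graph",
    "canonical_form_key",
    "canonical_labeling",
    "element_to_atomic_number",
    "graph_from_atoms",
    "graph_from_tucan",
    "hill_formula",
    "initial_partition",
    "molfile_from_tucan",
    "neighbor_atomic_numbers",
    "parse_molfile_v3000",
    "parse_tucan_string",
    "refine_partitions",
    "relabel",
    "serialize",
    "to_graph",
    "tucan_from_molfile",
    "write_molfile_v3000",
]
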