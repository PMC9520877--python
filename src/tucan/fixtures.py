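"""Curated fixture molecules, adversarial graphs and the shuffle test.

The fixture set mirrors the validation idea of covering the different
domains of chemistry rather than just organics:

* ``organic`` — drawn from SMILES (explicit hydrogens added), spanning
  tiny diatomics through drug-sized molecules;
* ``coordination`` — organometallic and coordination compounds built from
  explicit edge lists, since line notations cannot express their bonding
  (Zeise's anion, ferrocene, carbonyl and ammine complexes);
* ``cluster`` — main-group cages, rings and ion pairs, including
  disconnected and isotope/radical-labeled species;
* ``difficult-graph`` — highly symmetric, mostly vertex-transitive graphs
  (hypercubes, circulants, the Shrikhande/rook's-graph pair, ...) emitted
  as element-uniform all-carbon "molecules" so that only topology
  discriminates.  These challenge the canonicalization far harder than
  real molecules do.

The **shuffle test** is the validation protocol: permute the atom input
order many times, re-canonicalize, and require a single unique string.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable

import networkx as nx

from .graphs import build_graph
from .canonicalization import canonical_labeling
from .molfile import AtomRecord, BondRecord, MolfileData
from .serialization import serialize

CATEGORIES = ("organic", "coordination", "cluster", "difficult-graph")


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    category: str
    builder: Callable[[], MolfileData]


def molfile_data_from_atoms(
    elements: list[str],
    edges: list[tuple[int, int]],
    features: dict[int, dict[str, int]] | None = None,
) -> MolfileData:
    """Assemble MolfileData from 0-based element/edge/feature lists."""
    features = features or {}
    atoms = [
        AtomRecord(
            index=i + 1,
            element_symbol=symbol,
            charge=features.get(i, {}).get("CHG"),
            mass=features.get(i, {}).get("MASS"),
            radical=features.get(i, {}).get("RAD"),
        )
        for i, symbol in enumerate(elements)
    ]
    bonds = [BondRecord(a + 1, b + 1) for a, b in edges]
    return MolfileData(len(atoms), len(bonds), atoms, bonds)


def _from_smiles(smiles: str) -> MolfileData:
    """Build MolfileData from SMILES with all hydrogens made explicit."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"rdkit could not parse SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    elements = []
    features: dict[int, dict[str, int]] = {}
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        elements.append(atom.GetSymbol())
        fields: dict[str, int] = {}
        if atom.GetFormalCharge() != 0:
            fields["CHG"] = atom.GetFormalCharge()
        if atom.GetIsotope() != 0:
            fields["MASS"] = atom.GetIsotope()
        unpaired = atom.GetNumRadicalElectrons()
        if unpaired > 0:
            fields["RAD"] = min(unpaired + 1, 3)  # 2 = doublet, 3 = triplet
        if fields:
            features[i] = fields
    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return molfile_data_from_atoms(elements, edges, features)


def _from_nx(graph: nx.Graph, element: str = "C") -> MolfileData:
    graph = nx.convert_node_labels_to_integers(graph, ordering="sorted")
    return molfile_data_from_atoms(
        [element] * graph.number_of_nodes(),
        [(min(u, v), max(u, v)) for u, v in graph.edges],
    )


# --------------------------------------------------------------------------
# hand-built fixtures


def _zeise() -> MolfileData:
    """Zeise's anion [PtCl3(C2H4)]-: the worked serialization example.

    Atoms 0-1 ethylene carbons, 2-5 their hydrogens, 6-8 chlorides
    (CHG=-1 each), 9 the Pt center (CHG=2, MASS=196, explicit RAD=0).
    """
    return molfile_data_from_atoms(
        ["C", "C", "H", "H", "H", "H", "Cl", "Cl", "Cl", "Pt"],
        [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5), (0, 9), (1, 9), (6, 9), (7, 9), (8, 9)],
        {
            6: {"CHG": -1},
            7: {"CHG": -1},
            8: {"CHG": -1},
            9: {"CHG": 2, "MASS": 196, "RAD": 0},
        },
    )


def _bicyclooctenone() -> MolfileData:
    """Bicyclo[5.1.0]oct-1(7)-en-8-one with explicit H: 19 atoms.

    Carbons 0-6 form the seven-membered ring (0 and 6 are the fused
    bridgeheads), carbon 7 bridges them as the carbonyl carbon, node 8 is
    the ketone oxygen, nodes 9-18 are the CH2 hydrogens.
    """
    elements = ["C"] * 8 + ["O"] + ["H"] * 10
    edges = [(i, i + 1) for i in range(6)]  # ring chain C0..C6
    edges += [(6, 0), (0, 7), (6, 7), (7, 8)]
    hydrogen = 9
    for carbon in (1, 2, 3, 4, 5):  # each CH2 carries two hydrogens
        edges += [(carbon, hydrogen), (carbon, hydrogen + 1)]
        hydrogen += 2
    return molfile_data_from_atoms(elements, edges)


def _ferrocene() -> MolfileData:
    """Ferrocene: Fe bonded to all ten ring carbons, each carbon one H."""
    elements = ["Fe"] + ["C"] * 10 + ["H"] * 10
    edges = []
    for ring_start in (1, 6):
        ring = list(range(ring_start, ring_start + 5))
        edges += [(ring[i], ring[(i + 1) % 5]) for i in range(5)]
    edges += [(0, c) for c in range(1, 11)]
    edges += [(c, c + 10) for c in range(1, 11)]
    return molfile_data_from_atoms(elements, edges)


def _cisplatin() -> MolfileData:
    elements = ["Pt", "N", "N", "Cl", "Cl"] + ["H"] * 6
    edges = [(0, 1), (0, 2), (0, 3), (0, 4)]
    edges += [(1, 5), (1, 6), (1, 7), (2, 8), (2, 9), (2, 10)]
    return molfile_data_from_atoms(elements, edges)


def _chromium_hexacarbonyl() -> MolfileData:
    elements = ["Cr"] + ["C"] * 6 + ["O"] * 6
    edges = [(0, c) for c in range(1, 7)] + [(c, c + 6) for c in range(1, 7)]
    return molfile_data_from_atoms(elements, edges)


def _hexamminecobalt() -> MolfileData:
    """[Co(NH3)6]3+ with the charge carried on the metal center."""
    elements = ["Co"] + ["N"] * 6 + ["H"] * 18
    edges = [(0, n) for n in range(1, 7)]
    for n in range(1, 7):
        base = 7 + (n - 1) * 3
        edges += [(n, base), (n, base + 1), (n, base + 2)]
    return molfile_data_from_atoms(elements, edges, {0: {"CHG": 3}})


def _tetrachloroplatinate() -> MolfileData:
    """[PtCl4]2- as Pt(2+) with four chloride (CHG=-1) ligands."""
    return molfile_data_from_atoms(
        ["Pt", "Cl", "Cl", "Cl", "Cl"],
        [(0, 1), (0, 2), (0, 3), (0, 4)],
        {0: {"CHG": 2}, 1: {"CHG": -1}, 2: {"CHG": -1}, 3: {"CHG": -1}, 4: {"CHG": -1}},
    )


def _borane_cage(cage: nx.Graph) -> MolfileData:
    """closo-style cage: one terminal H per boron vertex."""
    cage = nx.convert_node_labels_to_integers(cage, ordering="sorted")
    n = cage.number_of_nodes()
    elements = ["B"] * n + ["H"] * n
    edges = [(min(u, v), max(u, v)) for u, v in cage.edges]
    edges += [(v, v + n) for v in range(n)]
    return molfile_data_from_atoms(elements, edges)


def _shrikhande() -> nx.Graph:
    """SRG(16,6,2,2) Cayley graph on Z4 x Z4; cospectral with rook-4."""
    graph = nx.Graph()
    offsets = [(1, 0), (3, 0), (0, 1), (0, 3), (1, 1), (3, 3)]
    for i in range(4):
        for j in range(4):
            for di, dj in offsets:
                graph.add_edge((i, j), ((i + di) % 4, (j + dj) % 4))
    return graph


_SMILES: dict[str, str] = {
    "helium": "[He]",
    "neon": "[Ne]",
    "argon": "[Ar]",
    "hydrogen": "[H][H]",
    "nitrogen": "N#N",
    "oxygen": "O=O",
    "hydrogen-chloride": "Cl",
    "carbon-monoxide": "[C-]#[O+]",
    "carbon-dioxide": "O=C=O",
    "hydrogen-cyanide": "C#N",
    "water": "O",
    "hydrogen-sulfide": "S",
    "ammonia": "N",
    "ammonium": "[NH4+]",
    "hydronium": "[OH3+]",
    "phosphine": "P",
    "silane": "[SiH4]",
    "hydrogen-peroxide": "OO",
    "hydrazine": "NN",
    "methane": "C",
    "formaldehyde": "C=O",
    "methanol": "CO",
    "formic-acid": "OC=O",
    "methylamine": "CN",
    "acetylene": "C#C",
    "ethylene": "C=C",
    "ethane": "CC",
    "acetaldehyde": "CC=O",
    "ethanol": "CCO",
    "acetic-acid": "CC(=O)O",
    "ethylene-glycol": "OCCO",
    "acetone": "CC(C)=O",
    "acetonitrile": "CC#N",
    "nitromethane": "C[N+](=O)[O-]",
    "dimethyl-ether": "COC",
    "dmso": "CS(C)=O",
    "propane": "CCC",
    "butane": "CCCC",
    "isobutane": "CC(C)C",
    "neopentane": "CC(C)(C)C",
    "cyclopropane": "C1CC1",
    "cyclobutane": "C1CCC1",
    "cyclopentane": "C1CCCC1",
    "cyclohexane": "C1CCCCC1",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "pyridine": "c1ccncc1",
    "furan": "c1ccoc1",
    "thiophene": "c1ccsc1",
    "pyrrole": "c1cc[nH]c1",
    "imidazole": "c1c[nH]cn1",
    "naphthalene": "c1ccc2ccccc2c1",
    "styrene": "C=Cc1ccccc1",
    "biphenyl": "c1ccc(-c2ccccc2)cc1",
    "glycine": "NCC(=O)O",
    "alanine": "CC(N)C(=O)O",
    "urea": "NC(N)=O",
    "glycerol": "OCC(O)CO",
    "glucose": "OCC1OC(O)C(O)C(O)C1O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "chloroform": "C(Cl)(Cl)Cl",
    "dichloromethane": "ClCCl",
    "tetrafluoromethane": "FC(F)(F)F",
    "sulfuric-acid": "OS(=O)(=O)O",
    "phosphoric-acid": "OP(=O)(O)O",
    "sulfur-hexafluoride": "FS(F)(F)(F)(F)F",
    "adamantane": "C1C2CC3CC1CC(C2)C3",
    "norbornane": "C1CC2CCC1C2",
}

_DIFFICULT: dict[str, Callable[[], nx.Graph]] = {
    "cycle-5": lambda: nx.cycle_graph(5),
    "cycle-8": lambda: nx.cycle_graph(8),
    "cycle-12": lambda: nx.cycle_graph(12),
    "complete-4": lambda: nx.complete_graph(4),
    "complete-6": lambda: nx.complete_graph(6),
    "bipartite-3-3": lambda: nx.complete_bipartite_graph(3, 3),
    "bipartite-4-4": lambda: nx.complete_bipartite_graph(4, 4),
    "cube-3": lambda: nx.hypercube_graph(3),
    "hypercube-4": lambda: nx.hypercube_graph(4),
    "petersen": nx.petersen_graph,
    "prism-6": lambda: nx.circular_ladder_graph(6),
    "wagner": lambda: nx.circulant_graph(8, [1, 4]),
    "moebius-kantor": nx.moebius_kantor_graph,
    "heawood": nx.heawood_graph,
    "paley-13": lambda: nx.circulant_graph(13, [1, 3, 4]),
    "shrikhande": _shrikhande,
    "rook-4": lambda: nx.cartesian_product(nx.complete_graph(4), nx.complete_graph(4)),
    "desargues": nx.desargues_graph,
    "dodecahedron": nx.dodecahedral_graph,
}


def _build_registry() -> dict[str, FixtureSpec]:
    registry: dict[str, FixtureSpec] = {}

    def add(name, category, builder):
        registry[name] = FixtureSpec(name, category, builder)

    for name, smiles in _SMILES.items():
        add(name, "organic", lambda s=smiles: _from_smiles(s))
    add("bicyclooctenone", "organic", _bicyclooctenone)

    add("zeise", "coordination", _zeise)
    add("ferrocene", "coordination", _ferrocene)
    add("cisplatin", "coordination", _cisplatin)
    add("chromium-hexacarbonyl", "coordination", _chromium_hexacarbonyl)
    add("hexamminecobalt", "coordination", _hexamminecobalt)
    add("tetrachloroplatinate", "coordination", _tetrachloroplatinate)

    add("white-phosphorus", "cluster", lambda: _from_nx(nx.complete_graph(4), "P"))
    add("sulfur-s8", "cluster", lambda: _from_nx(nx.cycle_graph(8), "S"))
    add("octahedral-borane", "cluster", lambda: _borane_cage(nx.octahedral_graph()))
    add("icosahedral-borane", "cluster", lambda: _borane_cage(nx.icosahedral_graph()))
    add(
        "sodium-chloride-ion-pair",
        "cluster",
        lambda: molfile_data_from_atoms(
            ["Na", "Cl"], [], {0: {"CHG": 1}, 1: {"CHG": -1}}
        ),
    )
    add("heavy-water", "cluster", lambda: _from_smiles("[2H]O[2H]"))
    add("semiheavy-water", "cluster", lambda: _from_smiles("[2H]O"))
    add("methyl-radical", "cluster", lambda: _from_smiles("[CH3]"))

    for name, thunk in _DIFFICULT.items():
        add(name, "difficult-graph", lambda t=thunk: _from_nx(t()))
    return registry


FIXTURES: dict[str, FixtureSpec] = _build_registry()


def fixture_names(category: str | None = None) -> list[str]:
    if category is not None and category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return [
        name
        for name, spec in FIXTURES.items()
        if category is None or spec.category == category
    ]


def generate_fixture(name: str) -> MolfileData:
    """Deterministically build the named fixture."""
    try:
        spec = FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}") from None
    return spec.builder()


def tucan_string(data: MolfileData) -> str:
    """Canonicalize and serialize parsed molfile data."""
    graph = build_graph(data)
    return serialize(graph, canonical_labeling(graph))


def permute_molfile(data: MolfileData, rng: random.Random) -> MolfileData:
    """Randomly permute the atom input order, remapping bonds consistently.

    Bond records are also shuffled and their endpoint order randomly
    flipped, so nothing about the original input order survives.
    """
    n = data.atom_count
    new_index = list(range(1, n + 1))
    rng.shuffle(new_index)  # atom i (1-based) becomes new_index[i-1]
    atoms: list[AtomRecord | None] = [None] * n
    for atom in data.atoms:
        moved = new_index[atom.index - 1]
        atoms[moved - 1] = AtomRecord(
            index=moved,
            element_symbol=atom.element_symbol,
            charge=atom.charge,
            mass=atom.mass,
            radical=atom.radical,
        )
    bonds = []
    for bond in data.bonds:
        a, b = new_index[bond.atom_a - 1], new_index[bond.atom_b - 1]
        if rng.random() < 0.5:
            a, b = b, a
        bonds.append(BondRecord(a, b))
    rng.shuffle(bonds)
    return MolfileData(n, data.bond_count, atoms, bonds)


@dataclass
class ShuffleReport:
    """Outcome of a shuffle (permutation) test on one structure."""

    permutations: int
    reference: str
    unique_strings: int
    mismatch: str | None = None  # first string differing from the reference

    @property
    def passed(self) -> bool:
        return self.unique_strings == 1


def shuffle_test(
    data: MolfileData,
    permutations: int = 100,
    seed: int = 0,
    serializer: Callable[[MolfileData], str] = tucan_string,
) -> ShuffleReport:
    """Permute the atom input order and require one unique string.

    ``serializer`` is injectable so the harness itself can be tested
    against a deliberately order-sensitive serializer.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = random.Random(seed)
    reference = serializer(data)
    seen = {reference}
    mismatch = None
    for _ in range(permutations):
        string = serializer(permute_molfile(data, rng))
        if string not in seen:
            seen.add(string)
            if mismatch is None:
                mismatch = string
    return ShuffleReport(
        permutations=permutations,
        reference=reference,
        unique_strings=len(seen),
        mismatch=mismatch,
    )
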