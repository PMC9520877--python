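"""Molfile v3000 parsing and writing."""

import pytest

from tucan import (
    MolfileParseError,
    UnknownElementError,
    build_graph,
    element_to_atomic_number,
    parse_molfile_v3000,
    write_molfile_v3000,
)

HELIUM_MOLFILE = """\
helium

  0  0  0     0  0            999 V3000
M  V30 BEGIN CTAB
M  V30 COUNTS 1 0 0 0 0
M  V30 BEGIN ATOM
M  V30 1 He 0.0 0.0 0.0 0
M  V30 END ATOM
M  V30 BEGIN BOND
M  V30 END BOND
M  V30 END CTAB
M  END
"""


class TestParse:
    def test_zeise_counts_and_fields(self, zeise_data):
        assert zeise_data.atom_count == 10
        assert zeise_data.bond_count == 10
        symbols = [a.element_symbol for a in zeise_data.atoms]
        assert symbols.count("H") == 4
        assert symbols.count("C") == 2
        assert symbols.count("Cl") == 3
        assert symbols.count("Pt") == 1
        platinum = zeise_data.atoms[9]
        assert platinum.features() == {"CHG": 2, "MASS": 196, "RAD": 0}
        # RAD=0 is explicitly present, not a default: the flag matters
        assert platinum.radical == 0
        for chloride in zeise_data.atoms[6:9]:
            assert chloride.features() == {"CHG": -1}
        # bond types and coordinates were discarded; only pairs remain
        assert {(b.atom_a, b.atom_b) for b in zeise_data.bonds} >= {(1, 2), (7, 10)}

    def test_minimal_single_atom(self):
        data = parse_molfile_v3000(HELIUM_MOLFILE)
        assert (data.atom_count, data.bond_count) == (1, 0)
        assert data.atoms[0].features() == {}

    def test_line_continuation(self, zeise_molfile):
        broken = zeise_molfile.replace(
            "M  V30 10 Pt 1.20 0.00 0.00 0 CHG=2 MASS=196 RAD=0",
            "M  V30 10 Pt 1.20 0.00 0.00 0 CHG=2 -\nM  V30 MASS=196 RAD=0",
        )
        data = parse_molfile_v3000(broken)
        assert data.atoms[9].features() == {"CHG": 2, "MASS": 196, "RAD": 0}

    @pytest.mark.parametrize(
        "mangle, message",
        [
            (lambda t: t.replace("M  V30 1 C ", "M  V30 1 * "), "pseudo-atom"),
            (lambda t: t.replace("M  V30 1 C ", "M  V30 1 Xx "), "unknown element"),
            (lambda t: t.replace("COUNTS 10 10", "COUNTS 11 10"), "ATOM block"),
            (lambda t: t.replace("COUNTS 10 10", "COUNTS 10 11"), "BOND block"),
            (lambda t: t.replace("M  V30 10 1 2 10", "M  V30 10 1 2 11"), "outside"),
            (lambda t: t.replace("M  V30 10 1 2 10", "M  V30 10 1 2 2"), "self-bond"),
            (lambda t: t.replace("M  V30 10 1 2 10", "M  V30 10 1 1 2"), "duplicate"),
            (lambda t: t.replace("M  V30 BEGIN CTAB\n", ""), "BEGIN CTAB"),
            (lambda t: t.replace("M  V30 COUNTS 10 10 0 0 0\n", ""), "COUNTS"),
        ],
    )
    def test_fatal_inputs(self, zeise_molfile, mangle, message):
        with pytest.raises((MolfileParseError, UnknownElementError), match=message):
            parse_molfile_v3000(mangle(zeise_molfile))

    def test_not_v3000(self):
        with pytest.raises(MolfileParseError):
            parse_molfile_v3000("just some text\n")


class TestElementLookup:
    @pytest.mark.parametrize("symbol, z", [("H", 1), ("C", 6), ("Pt", 78), ("Og", 118)])
    def test_valid_symbols(self, symbol, z):
        assert element_to_atomic_number(symbol) == z

    @pytest.mark.parametrize("symbol", ["h", "XX", "", "D", "c"])
    def test_invalid_symbols(self, symbol):
        with pytest.raises(UnknownElementError):
            element_to_atomic_number(symbol)

    def test_star_atom_has_dedicated_message(self):
        with pytest.raises(UnknownElementError, match="pseudo-atom"):
            element_to_atomic_number("*")


class TestWrite:
    def test_round_trip_preserves_retained_fields(self, zeise_data):
        rewritten = parse_molfile_v3000(write_molfile_v3000(build_graph(zeise_data)))
        assert rewritten.atom_count == zeise_data.atom_count
        assert rewritten.bond_count == zeise_data.bond_count
        for original, copy in zip(zeise_data.atoms, rewritten.atoms):
            assert copy.element_symbol == original.element_symbol
            assert copy.features() == original.features()
        edges = lambda d: {tuple(sorted((b.atom_a, b.atom_b))) for b in d.bonds}
        assert edges(rewritten) == edges(zeise_data)

    def test_written_file_shape(self, zeise_graph):
        text = write_molfile_v3000(zeise_graph)
        assert "M  V30 COUNTS 10 10 0 0 0" in text
        assert "CHG=2 MASS=196 RAD=0" in text
        assert "V3000" in text.splitlines()[3]

    def test_h2_molfile(self):
        from tucan.graphs import graph_from_atoms

        text = write_molfile_v3000(graph_from_atoms(["H", "H"], [(0, 1)]))
        data = parse_molfile_v3000(text)
        assert (data.atom_count, data.bond_count) == (2, 1)
        assert all(a.element_symbol == "H" for a in data.atoms)
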