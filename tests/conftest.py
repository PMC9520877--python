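import pytest

# Zeise's anion, [PtCl3(C2H4)]-, drawn with explicit hydrogens.  The C=C
# bond is written as type 2 and coordinates are non-zero on purpose: both
# must be discarded by the parser.
ZEISE_MOLFILE = """\
Zeise's anion
  test fixture

  0  0  0     0  0            999 V3000
M  V30 BEGIN CTAB
M  V30 COUNTS 10 10 0 0 0
M  V30 BEGIN ATOM
M  V30 1 C -0.77 0.50 0.00 0
M  V30 2 C -0.77 -0.50 0.00 0
M  V30 3 H -1.43 1.00 0.00 0
M  V30 4 H -0.11 1.00 0.00 0
M  V30 5 H -1.43 -1.00 0.00 0
M  V30 6 H -0.11 -1.00 0.00 0
M  V30 7 Cl 1.87 1.00 0.00 0 CHG=-1
M  V30 8 Cl 1.87 -1.00 0.00 0 CHG=-1
M  V30 9 Cl 2.87 0.00 0.00 0 CHG=-1
M  V30 10 Pt 1.20 0.00 0.00 0 CHG=2 MASS=196 RAD=0
M  V30 END ATOM
M  V30 BEGIN BOND
M  V30 1 2 1 2
M  V30 2 1 1 3
M  V30 3 1 1 4
M  V30 4 1 2 5
M  V30 5 1 2 6
M  V30 6 1 7 10
M  V30 7 1 8 10
M  V30 8 1 9 10
M  V30 9 1 1 10
M  V30 10 1 2 10
M  V30 END BOND
M  V30 END CTAB
M  END
"""

ZEISE_STRING = (
    "C2H4Cl3Pt/(1-5)(2-5)(3-6)(4-6)(5-6)(5-10)(6-10)(7-10)(8-10)(9-10)"
    "/(7:CHG=-1)(8:CHG=-1)(9:CHG=-1)(10:CHG=2,MASS=196,RAD=0)"
)


@pytest.fixture
def zeise_molfile():
    return ZEISE_MOLFILE


@pytest.fixture
def zeise_data():
    from tucan import parse_molfile_v3000

    return parse_molfile_v3000(ZEISE_MOLFILE)


@pytest.fixture
def zeise_graph(zeise_data):
    from tucan import build_graph

    return build_graph(zeise_data)


@pytest.fixture
def bicyclooctenone_graph():
    from tucan import build_graph
    from tucan.fixtures import generate_fixture

    return build_graph(generate_fixture("bicyclooctenone"))
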