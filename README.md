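# tucan-id

A canonical, bidirectional, tuple-style molecular identifier and descriptor
applicable to the whole periodic table, from hydrogen to oganesson.

Classical line notations lean on Lewis-structure concepts — bond orders,
standard valences, implicit hydrogens, aromaticity — that work well for
organic molecules and break down for organometallic, coordination,
main-group and cluster compounds (think ferrocene's ten equivalent Fe–C
contacts, or multi-center bonding in boranes).  This package implements the
TUCAN ("tuple canonicalization") format, which sidesteps all of that: a
molecule is an undirected labeled graph with explicit hydrogens, the only
chemistry-specific invariant is the atomic number, and bond types are
deliberately discarded.  What the user connects in the molfile bond block
is an edge; nothing else matters.

It is aimed at cheminformaticians and inorganic/organometallic chemists who
need stable identifiers for molecules that InChI and SMILES cannot
represent faithfully — and at anyone who wants an identifier that can be
decoded back into the molecular graph.

## The identifier

For a molecular graph `G = (V, E)` with atomic numbers `Z(v)`, the string is

```
Hill formula / edge 2-tuples / node features
```

computed in three stages:

1. **Invariant codes** — every atom gets the code
   `(Z(v), {Z(u) : u ∈ N(v)})`, its atomic number followed by the multiset
   of neighbor atomic numbers sorted in decreasing order.  Atoms with
   identical codes share an initial partition.
2. **Refinement** — partitions are refined with the 1-dimensional
   Weisfeiler–Lehman (Morgan) algorithm: two atoms separate when they are
   adjacent to different multisets of partitions; iterate to the stable
   (equitable) partition.
3. **Canonical labeling** — remaining symmetry is broken by
   individualization–refinement: each member of the first non-singleton
   cell is provisionally singled out, refinement is re-run, and the branch
   whose discrete labeling minimizes the serialized form (edge list, then
   feature list) wins.  Automorphism pruning keeps highly symmetric graphs
   (hypercubes, strongly regular graphs) tractable.

Output labels `1..n` are assigned in increasing atomic-number order, so the
formula alone reveals which label is which element.  Optional molfile atom
fields `CHG` (formal charge), `MASS` (isotope mass number) and `RAD`
(radical code) are carried in the feature block; they never influence the
canonical labeling of the topology.  The string is bijective under
atom-order permutation and can be expanded back into a coordinate-free
molfile v3000, so it doubles as a descriptor.

## Worked example: Zeise's anion

Zeise's salt, K[PtCl₃(C₂H₄)]·H₂O, is the classic organometallic test case;
its anion has a Pt center bonded to three chlorides and *both* ethylene
carbons — unproblematic here, since the π complex is just five edges at Pt.

```sh
$ tucan fixture zeise | tucan serialize -
C2H4Cl3Pt/(1-5)(2-5)(3-6)(4-6)(5-6)(5-10)(6-10)(7-10)(8-10)(9-10)/(7:CHG=-1)(8:CHG=-1)(9:CHG=-1)(10:CHG=2,MASS=196,RAD=0)
```

Reading the string: the Hill formula `C2H4Cl3Pt` says the molecule has 2 C,
4 H, 3 Cl and 1 Pt.  Labels increase with atomic number, so labels 1–4 are
the hydrogens, 5–6 the carbons, 7–9 the chlorides, 10 the platinum.  The
first four tuples are the C–H bonds, `(5-6)` is the C–C bond, `(5-10)` and
`(6-10)` the two Pt–C contacts, and the last three the Pt–Cl bonds.  The
feature block records the chloride charges, and for Pt a formal charge of
+2, the ¹⁹⁶Pt isotope, and an explicitly written `RAD=0`.

The string decodes back into a molfile:

```sh
$ tucan deserialize "Ne"            # monoatomic: formula-only string
$ tucan serialize - < some.mol      # molfile from stdin
$ tucan shuffle-test some.mol --n 100 --seed 7
PASS: 1 unique string over 100 permutations
$ tucan trace some.mol              # per-round refinement partitions
```

The same API is available from Python:

```python
>>> from tucan import tucan_from_molfile, molfile_from_tucan
>>> from tucan.fixtures import generate_fixture, tucan_string
>>> tucan_string(generate_fixture("methane"))
'CH4/(1-5)(2-5)(3-5)(4-5)'
```

## Fixture library

`tucan.fixtures` ships >100 deterministic test structures spanning organic
molecules (diatomics to caffeine and ibuprofen), coordination and
organometallic compounds (Zeise's anion, ferrocene, cisplatin, carbonyl and
ammine complexes), main-group clusters and isotope/radical species, plus a
library of highly symmetric element-uniform "difficult graphs" (hypercubes,
circulants, Petersen, Heawood, the cospectral Shrikhande/rook's-graph
pair) designed to stress the canonicalization far harder than chemistry
does.  `tucan fixture --list` enumerates them.

## Scope

Stereochemistry is not encoded (diastereomers and enantiomers collide), the
`*` pseudo-atom and multi-center bond blocks are rejected with a clear
error, implicit hydrogens are never invented, and v2000 molfiles are not
read.  See `docs/methods.md` for the full design discussion.
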