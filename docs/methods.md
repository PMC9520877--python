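# Methods

## Model of a molecule

A molecule is an undirected labeled graph without multi-edges or loops:
atoms are nodes, bonds are edges.  Which atoms are bonded is taken verbatim
from the molfile v3000 bond block; bond *types* are discarded, because bond
orders are a domain-specific bookkeeping device that does not generalize
beyond organic chemistry (and molfile types 5/6 are already overloaded).
All hydrogens must be explicit: there is no algorithmic way to decide how
many implicit hydrogens a metal center or its ligand atoms should carry, so
none are ever invented.  Atoms the file does not contain do not exist;
"hydrogen-pruned" inputs canonicalize fine but describe a different graph.

The only chemistry-specific node invariant is the atomic number (valid
range: elements 1–118).  Formal charge, isotope mass number and radical
code (molfile `CHG`/`MASS`/`RAD`) are carried as *node features*: they are
serialized, and they survive round trips, but they do not participate in
canonicalization invariants.  Presence is tracked separately from value —
an explicit `RAD=0` in the input is preserved and emitted, an absent field
is not.  Custom display attributes (e.g. element colors) may be attached to
nodes but are excluded from every comparison, enforced by test.

## Canonicalization

1. **Invariant codes.**  Each node's code is
   `(Z, multiset of neighbor Zs, decreasing)`.  The code implicitly fixes
   the degree, so nodes in one cell always share a degree.
2. **Initial partition.**  Nodes with equal codes share a cell.  Cells are
   *ordered*: ascending atomic number first, then by the neighbor multiset
   compared elementwise ascending, with a prefix tie resolved toward the
   longer multiset.  Equivalently, the multiset is padded with a sentinel
   larger than any atomic number; this puts higher-degree environments of
   the same element first.  The rule was chosen so that, on small graphs,
   the final search minimum coincides with the brute-force lexicographic
   minimum over all element-respecting labelings — which is how the stage
   is validated (see Testing).
3. **Weisfeiler–Lehman refinement.**  Each round recomputes every cell's
   split from `(old cell index, sorted multiset of neighbor cell indices)`;
   sub-cells replace their parent in place, ordered by ascending key, and
   rounds repeat until no cell splits.  Refinement never merges cells, so
   the stable partition refines the initial one; it is also idempotent.
   No incremental optimization is attempted — the naive recomputation is a
   few microseconds per round at fixture scale.
4. **Individualization–refinement.**  If the stable partition is discrete,
   the labeling is read straight from cell order.  Otherwise the search
   takes the *first* non-singleton cell in partition order, branches on
   individualizing each of its members (moved into a new singleton cell
   directly before its remainder), re-refines, and recurses.  Every leaf
   is a discrete partition, i.e. a candidate labeling; the canonical form
   is the minimum leaf key, where the key is the serialized edge list
   followed by the feature list under that labeling, tuples compared
   numerically.  Because cell order, refinement keys and the leaf key are
   all content-based, the minimum is invariant under any permutation of
   the input atom order.

### Automorphism pruning

Exhaustive leaf enumeration is factorial on symmetric, element-uniform
graphs.  The search therefore records, whenever a leaf reproduces the
current best key *and* places the individualized base vertices at the same
canonical positions, that the two search paths are related by a graph
automorphism.  The subtree rooted at the first base divergence is then
abandoned: an automorphic subtree cannot contain a smaller minimum.  This
is the classical pruning idea behind canonical-labeling tools; here only
the best-path variant is implemented, which already reduces the explored
tree to roughly automorphism-group size.  The 4-dimensional hypercube
(|Aut| = 384) and the rook's 4×4 graph (|Aut| = 1152) canonicalize in tens
of milliseconds; no fixture needs more.

The choice of target cell (first non-singleton) and member order affect
performance only, never the result, since the minimum ranges over all
branches.

### Features and symmetry

Features are excluded from the invariant codes: two atoms that differ only
in charge, isotope or radical state land in the same cell, matching the
principle that canonicalization depends on topology and atomic number
alone.  The feature list still enters the *leaf key*, after the edge list,
as a final tie-break.  Consequences, both covered by test:

* for molecules whose refinement is discrete, altering features changes
  only the feature block, never the labeling;
* for molecules with features on symmetry-equivalent atoms (e.g.
  semi-heavy water, HDO), the tie-break picks a deterministic
  representative among the automorphic labelings, so the shuffle test
  still yields a single unique string.

## Serialization

Output labels `1..n` are assigned by ascending atomic number, ties broken
by canonical label; since the ordered partition is already grouped by
element, this is a formality.  The string is
`formula[/edges][/features]`:

* Hill formula — C first, then H, then the other elements alphabetically;
  with no carbon, everything alphabetical (standard Hill convention);
  counts of 1 omit the digit.
* Edge tuples `(a-b)` with `a < b`, the list sorted by `(a, b)`; each edge
  appears once.
* Feature entries `(label:FIELD=VALUE,...)`, fields sorted by name
  (CHG < MASS < RAD), entries by label, no whitespace, ASCII throughout
  (signed charges use the ASCII hyphen).

Empty blocks are omitted: a noble-gas atom serializes as its formula, a
disconnected ion pair as formula + features.  A fourth block is reserved
for custom data; the parser accepts and preserves one verbatim but the
serializer never emits it.

## Deserialization

The formula expands to per-label elements by ascending atomic number —
deliberately *not* Hill print order (Zeise's formula starts with C, its
labels with H).  The parser validates the grammar strictly: sorted
ascending edge tuples, in-range labels, no duplicate edges, known field
names, sorted feature entries.  Grammatical but non-canonical strings
(labels permuted within an element) build a valid graph and simply
re-canonicalize; `strict` mode rejects any string whose re-serialization
differs.  Reconstructed molfiles are coordinate-free: zeroed coordinates,
all bonds type 1, features emitted only when present.

## Fixture suite and the shuffle test

The suite (106 structures) is generated programmatically and is
bit-reproducible: organic molecules from SMILES via RDKit with hydrogens
made explicit; coordination/organometallic compounds and clusters from
hand-written edge lists (line notations cannot express them); difficult
graphs from networkx generators, emitted as all-carbon molecules so only
topology discriminates.  The difficult set includes vertex-transitive
families (cycles, complete and complete-bipartite graphs, hypercubes,
circulants including a Paley graph, prisms, Petersen/Heawood/Desargues/
Möbius–Kantor) and the Shrikhande vs. 4×4 rook's graph pair — cospectral
strongly regular graphs SRG(16,6,2,2) that 1-D WL cannot distinguish but
individualization–refinement must (and does: they get distinct strings).

Validation protocol: the **shuffle test** permutes the atom input order
(with consistent bond remapping and random endpoint flips), re-runs the
whole pipeline, and requires exactly one unique string.  The default is
100 permutations per structure with a fixed recorded seed; the full suite
runs in under ten seconds on one CPU.

What the fixtures do *not* emulate: stereochemistry, multi-center bond
blocks, polymer/disorder records, and database-scale input volume.  A
passing suite shows order-invariance and bidirectionality of the encoding
at desk scale, not chemical validity checking — the molfile is trusted.

## Small-graph oracle

`brute_force_canonical` enumerates *all* labelings in which positions
increase with atomic number (product of per-element factorials, refused
above 8 atoms) and returns the minimal key.  It shares no code path with
the search beyond the key function itself.  Every fixture with ≤ 8 atoms —
53 structures, including the element-uniform symmetric graphs — must agree
exactly with the individualization–refinement result.

## Numerical and degenerate-input choices

* Deterministic throughout; the only randomness is the shuffle test's
  permutation stream, seeded explicitly.
* Disconnected inputs are accepted (the format covers them); duplicate
  bonds, self-bonds and out-of-range endpoints are fatal parse errors
  rather than silently repaired.
* `RAD` outside 0–3 is rejected; unknown ATOM-block keywords are ignored
  (only CHG/MASS/RAD are meaningful to the format).
* The `*` pseudo-atom gets a dedicated error message since it is legal
  CTFile syntax that this format intentionally does not cover.

## Known limitations

* No stereochemistry: enantiomers and diastereomers receive identical
  strings.
* Tautomers receive different strings (they are different graphs).
* The identifier is verbose relative to InChI/SMILES — roughly 2× and 4×
  respectively on protein-sized inputs — the price of explicit tuples.
* Performance degrades on pathological inputs whose automorphism groups
  defeat best-path pruning (large projective-plane incidence graphs and
  the like); chemistry-scale inputs, including small proteins, are far
  from that regime.
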