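"""Invariant codes, partition refinement and canonical labeling."""

import random

import pytest

from tucan import (
    assign_invariant_codes,
    brute_force_canonical,
    build_graph,
    canonical_form_key,
    canonical_labeling,
    initial_partition,
    refine_partitions,
    serialize,
)
from tucan.graphs import graph_from_atoms
from tucan.fixtures import (
    fixture_names,
    generate_fixture,
    permute_molfile,
    tucan_string,
)


def _benzene():
    ring = [(i, (i + 1) % 6) for i in range(6)]
    hydrogens = [(i, i + 6) for i in range(6)]
    return graph_from_atoms(["C"] * 6 + ["H"] * 6, ring + hydrogens)


class TestInvariantCodes:
    def test_benzene_codes(self):
        codes = assign_invariant_codes(_benzene())
        for v in range(6):
            assert codes[v] == (6, (6, 6, 1))
        for v in range(6, 12):
            assert codes[v] == (1, (6,))

    def test_isolated_helium(self):
        codes = assign_invariant_codes(graph_from_atoms(["He"], []))
        assert codes == {0: (2, ())}

    def test_bicyclooctenone_five_distinct_codes(self, bicyclooctenone_graph):
        codes = assign_invariant_codes(bicyclooctenone_graph)
        assert len(set(codes.values())) == 5


class TestInitialPartition:
    def test_bicyclooctenone_five_partitions(self, bicyclooctenone_graph):
        partition = initial_partition(assign_invariant_codes(bicyclooctenone_graph))
        assert len(partition) == 5

    def test_h2_single_partition(self):
        graph = graph_from_atoms(["H", "H"], [(0, 1)])
        assert len(initial_partition(assign_invariant_codes(graph))) == 1

    def test_distinct_codes_give_singletons(self):
        graph = graph_from_atoms(["H", "O", "Cl"], [(0, 1)])
        partition = initial_partition(assign_invariant_codes(graph))
        assert partition.is_discrete()

    def test_partition_indices_contiguous(self, zeise_graph):
        partition = initial_partition(assign_invariant_codes(zeise_graph))
        assignment = partition.assignment
        assert set(assignment) == set(zeise_graph.nodes)
        assert set(assignment.values()) == set(range(len(partition)))


class TestRefinement:
    def test_monotone_and_idempotent(self, bicyclooctenone_graph):
        initial = initial_partition(assign_invariant_codes(bicyclooctenone_graph))
        stable = refine_partitions(bicyclooctenone_graph, initial)
        assert len(stable) >= len(initial)
        assert refine_partitions(bicyclooctenone_graph, stable).cells == stable.cells

    def test_discrete_partition_is_fixed_point(self):
        graph = graph_from_atoms(["H", "O", "Cl"], [(0, 1)])
        discrete = initial_partition(assign_invariant_codes(graph))
        assert refine_partitions(graph, discrete).cells == discrete.cells

    def test_vertex_transitive_ring_does_not_split(self):
        """Benzene's symmetry leaves the C/H partition untouched."""
        graph = _benzene()
        initial = initial_partition(assign_invariant_codes(graph))
        stable = refine_partitions(graph, initial)
        assert len(stable) == len(initial) == 2

    def test_never_merges(self, bicyclooctenone_graph):
        initial = initial_partition(assign_invariant_codes(bicyclooctenone_graph))
        before = initial.assignment
        after = refine_partitions(bicyclooctenone_graph, initial).assignment
        for u in before:
            for v in before:
                if before[u] != before[v]:
                    assert after[u] != after[v]


class TestCanonicalLabeling:
    def test_bijection(self, zeise_graph):
        canon = canonical_labeling(zeise_graph)
        assert sorted(canon) == sorted(zeise_graph.nodes)
        assert sorted(canon.values()) == list(range(10))

    def test_discrete_partition_read_directly(self):
        graph = graph_from_atoms(["H", "O", "Cl"], [(0, 1)])
        stable = refine_partitions(
            graph, initial_partition(assign_invariant_codes(graph))
        )
        assert stable.is_discrete()
        canon = canonical_labeling(graph, stable)
        expected = {cell[0]: i for i, cell in enumerate(stable.cells)}
        assert canon == expected

    def test_four_cycle_matches_brute_force(self):
        graph = graph_from_atoms(["C"] * 4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert canonical_form_key(graph) == brute_force_canonical(graph)

    def test_shuffle_invariance_zeise(self, zeise_data):
        rng = random.Random(7)
        reference = tucan_string(zeise_data)
        for _ in range(25):
            assert tucan_string(permute_molfile(zeise_data, rng)) == reference

    def test_features_do_not_change_topology_labeling(self):
        """CHG/MASS/RAD alter the feature block only, not the labeling.

        Checked on a molecule whose refinement is discrete, so the claim
        is exact: glucose has no topological symmetry.
        """
        plain = build_graph(generate_fixture("glucose"))
        canon_plain = canonical_labeling(plain)
        charged = plain.copy()
        target = max(charged.nodes, key=lambda v: canon_plain[v])
        charged.nodes[target]["features"] = {"CHG": 1, "MASS": 13}
        assert canonical_labeling(charged) == canon_plain
        plain_string, charged_string = serialize(plain), serialize(charged)
        assert plain_string != charged_string
        assert charged_string.startswith(plain_string)  # extra feature block


class TestBruteForceOracle:
    def test_h2_single_form(self):
        graph = graph_from_atoms(["H", "H"], [(0, 1)])
        assert brute_force_canonical(graph) == (((1, 2),), ())

    def test_methane_matches_search(self):
        graph = build_graph(generate_fixture("methane"))
        assert canonical_form_key(graph) == brute_force_canonical(graph)

    def test_wagner_graph_matches_search(self):
        """8-node vertex-transitive circulant: element-uniform symmetry."""
        graph = build_graph(generate_fixture("wagner"))
        assert canonical_form_key(graph) == brute_force_canonical(graph)

    def test_refuses_large_graphs(self, bicyclooctenone_graph):
        with pytest.raises(ValueError, match="refused"):
            brute_force_canonical(bicyclooctenone_graph)


def test_shuffle_invariance_across_categories():
    """A quick desk-scale permutation check on one fixture per category."""
    rng = random.Random(11)
    for name in ("caffeine", "ferrocene", "icosahedral-borane", "petersen"):
        data = generate_fixture(name)
        reference = tucan_string(data)
        for _ in range(10):
            assert tucan_string(permute_molfile(data, rng)) == reference, name
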