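"""Finishing complexity, C-statistic, repeat bins, tuned insert sizes."""

import pytest

from matetune import (
    Genome,
    GenomePlan,
    RepeatSpec,
    bin_repeat_complexity,
    build_graph,
    c_statistic,
    classify_triviality,
    complexity_report,
    generate_genome,
    graph_finishing_complexity,
    node_finishing_complexity,
    simplify,
    tuned_library_sizes,
)
from matetune.graph import KmerGraph


def sequential_pairing_experiments(a: int) -> int:
    """Independent oracle: worst-case count of targeted experiments needed
    to pair all in/out edges of a degree-a repeat by trying an arbitrary
    in-edge against candidate out-edges (the last pairing is implicit)."""
    experiments = 0
    while a > 1:
        experiments += a - 1  # correct out-edge found on the last attempt
        a -= 1
    return experiments


def toy_graph(edges, labels):
    """Hand-built simplified graph for metric unit tests."""
    kg = KmerGraph(k=5, genome_length=sum(len(l) - 3 for l in labels.values()),
                   circular=True)
    ids = {}
    for name, label in labels.items():
        ids[name] = kg.new_node(label, [0])
    for u, v in edges:
        kg.g.add_edge(ids[u], ids[v], coord=-1)
    return kg, ids


class TestNodeComplexity:
    @pytest.mark.parametrize("a", range(9))
    def test_matches_pairing_simulation(self, a):
        assert node_finishing_complexity(a) == sequential_pairing_experiments(a)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            node_finishing_complexity(-1)

    def test_graph_total_is_additive(self, array_graph):
        # one degree-4 node, everything else degree 1
        assert graph_finishing_complexity(array_graph) == 6


class TestTriviality:
    def test_distinct_successor_lengths_trivial(self):
        kg, ids = toy_graph(
            [("A", "R"), ("B", "R"), ("R", "A"), ("R", "B")],
            {"R": "x" * 30, "A": "x" * 120, "B": "x" * 340})
        assert classify_triviality(kg, ids["R"]) is True
        assert c_statistic(kg) == 0.0

    def test_equal_successor_lengths_non_trivial(self):
        kg, ids = toy_graph(
            [("A", "R"), ("B", "R"), ("R", "A"), ("R", "B")],
            {"R": "x" * 30, "A": "x" * 200, "B": "x" * 200})
        assert classify_triviality(kg, ids["R"]) is False
        assert c_statistic(kg) == 100.0

    def test_parallel_out_edges_non_trivial(self):
        kg, ids = toy_graph(
            [("A", "R"), ("B", "R"), ("R", "W"), ("R", "W"), ("W", "A"), ("W", "B")],
            {"R": "x" * 30, "A": "x" * 100, "B": "x" * 150, "W": "x" * 60})
        assert classify_triviality(kg, ids["R"]) is False

    def test_non_decision_node_rejected(self):
        kg, ids = toy_graph([("A", "R"), ("R", "A")], {"R": "x" * 30, "A": "x" * 99})
        with pytest.raises(ValueError):
            classify_triviality(kg, ids["A"])

    def test_mixed_graph_half_non_trivial(self):
        kg, ids = toy_graph(
            [("A", "R"), ("B", "R"), ("R", "A"), ("R", "B"),
             ("C", "Q"), ("D", "Q"), ("Q", "C"), ("Q", "D")],
            {"R": "x" * 30, "A": "x" * 200, "B": "x" * 200,
             "Q": "x" * 40, "C": "x" * 110, "D": "x" * 260})
        assert c_statistic(kg) == 50.0


class TestCStatFixtures:
    def test_bubble_fixture_is_fully_non_trivial(self, bubble_graph):
        assert c_statistic(bubble_graph) == 100.0

    def test_distinct_flank_repeat_is_trivial(self, three_copy_genome):
        sg = simplify(build_graph(three_copy_genome, 50))
        assert graph_finishing_complexity(sg) == 3
        assert c_statistic(sg) == 0.0

    def test_zero_complexity_graph_has_zero_c_stat(self, single_repeat_genome):
        sg = simplify(build_graph(single_repeat_genome, 50))
        assert graph_finishing_complexity(sg) == 0
        assert c_statistic(sg) == 0.0


class TestBinsAndTuning:
    def test_bin_arithmetic(self):
        kg, ids = toy_graph(
            [("A", "R"), ("B", "R"), ("R", "A"), ("R", "B"),
             ("C", "Q"), ("D", "Q"), ("Q", "C"), ("Q", "D")],
            {"R": "x" * 150, "A": "x" * 210, "B": "x" * 320,
             "Q": "x" * 700, "C": "x" * 400, "D": "x" * 500})
        bins = bin_repeat_complexity(kg, k=50)  # width 200
        assert [(b.lo, b.hi) for b in bins] == [(0, 200), (600, 800)]
        assert sum(b.complexity_share for b in bins) == pytest.approx(1.0)

    def test_boundary_length_goes_to_upper_bin(self):
        kg, ids = toy_graph(
            [("A", "R"), ("B", "R"), ("R", "A"), ("R", "B")],
            {"R": "x" * 200, "A": "x" * 300, "B": "x" * 410})
        (b,) = bin_repeat_complexity(kg, k=50)
        assert (b.lo, b.hi) == (200, 400)

    def test_single_bin_insert(self):
        kg, ids = toy_graph(
            [("A", "R"), ("B", "R"), ("R", "A"), ("R", "B")],
            {"R": "x" * 300, "A": "x" * 400, "B": "x" * 510})
        plan = tuned_library_sizes(kg, k=50)
        assert plan.insert_sizes == (450,)

    def test_two_bin_inserts_sorted(self):
        kg, ids = toy_graph(
            [("A", "R"), ("B", "R"), ("R", "A"), ("R", "B"),
             ("C", "Q"), ("D", "Q"), ("Q", "C"), ("Q", "D")],
            {"R": "x" * 110, "A": "x" * 200, "B": "x" * 320,
             "Q": "x" * 320, "C": "x" * 400, "D": "x" * 515})
        plan = tuned_library_sizes(kg, k=35)
        assert plan.insert_sizes == (215, 425)

    def test_tie_break_prefers_smaller_bin(self):
        # equal complexity in two bins: the shorter-insert bin is listed first
        kg, ids = toy_graph(
            [("A", "R"), ("B", "R"), ("R", "A"), ("R", "B"),
             ("C", "Q"), ("D", "Q"), ("Q", "C"), ("Q", "D")],
            {"R": "x" * 100, "A": "x" * 210, "B": "x" * 330,
             "Q": "x" * 600, "C": "x" * 410, "D": "x" * 520})
        plan = tuned_library_sizes(kg, k=50, n_libraries=1)
        assert plan.insert_sizes == (100 + 150,)

    def test_no_decision_nodes_yields_empty_plan(self, single_repeat_genome):
        sg = simplify(build_graph(single_repeat_genome, 50))
        assert tuned_library_sizes(sg, 50).empty

    def test_report_consistency(self, bubble_graph):
        rep = complexity_report(bubble_graph, 35)
        assert rep.total_complexity == graph_finishing_complexity(bubble_graph)
        assert rep.c_statistic == c_statistic(bubble_graph)
        assert (rep.table["complexity"] > 0).sum() == len(bubble_graph.decision_nodes())
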