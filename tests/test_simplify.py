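"""Lossless graph simplification: compression, unzipping, unique-tour collapse."""

import numpy as np
import pytest

from matetune import (
    Genome,
    GenomePlan,
    RepeatSpec,
    build_graph,
    collapse_unique_tour_components,
    compress_unambiguous_paths,
    enumerate_eulerian,
    generate_genome,
    simplify,
    unzip_half_decision_nodes,
)

from conftest import random_plan, random_sequence


class TestCompress:
    def test_linear_path_graph_collapses_to_genome(self):
        kg = build_graph(Genome("t", "AAGCTT", circular=False), 3)
        out = compress_unambiguous_paths(kg)
        assert out.n_nodes() == 1
        assert out.label(out.nodes()[0]) == "AAGCTT"

    def test_idempotent(self, array_graph):
        out = compress_unambiguous_paths(array_graph)
        assert {out.label(n) for n in out.nodes()} == {
            array_graph.label(n) for n in array_graph.nodes()}

    def test_self_loop_not_merged_with_itself(self):
        kg = build_graph(Genome("t", "AAAA", circular=False), 3)
        out = compress_unambiguous_paths(kg)
        assert out.n_nodes() == 1
        assert out.g.number_of_edges() == 2  # self-loop instances survive

    def test_repeat_body_merges_to_full_length_node(self, three_copy_genome):
        kg = compress_unambiguous_paths(build_graph(three_copy_genome, 50))
        labels = sorted(len(kg.label(n)) for n in kg.nodes()
                        if kg.in_deg(n) >= 2)
        assert labels == [300]  # the repeat node spells the whole unit


class TestUnzip:
    def test_fully_decided_graph_unchanged(self, array_graph):
        out = unzip_half_decision_nodes(array_graph)
        assert {out.label(n) for n in out.nodes()} == {
            array_graph.label(n) for n in array_graph.nodes()}

    def test_unzip_preserves_traversals(self):
        # adjacent distinct repeats create half-decision chains after
        # compression; spellings must be preserved through unzipping
        for seed in (23, 31, 47):
            plan = random_plan(seed)
            g = generate_genome(plan)
            kg = build_graph(g, plan.k_guard)
            pre = enumerate_eulerian(kg, cap=512)
            out = unzip_half_decision_nodes(compress_unambiguous_paths(kg))
            assert enumerate_eulerian(out, cap=512) == pre


class TestCollapse:
    def test_lone_two_copy_repeat_has_unique_tour_and_collapses(self, single_repeat_genome):
        kg = build_graph(single_repeat_genome, 50)
        assert len(enumerate_eulerian(kg, cap=64)) == 1  # figure-eight: one cyclic tour
        sg = simplify(kg)
        assert sg.n_nodes() == 1 and sg.n_edge_instances() == 0

    def test_ambiguous_graph_left_untouched(self, three_copy_genome):
        kg = build_graph(three_copy_genome, 50)
        assert len(enumerate_eulerian(kg, cap=64)) == 2
        sg = simplify(kg)
        assert sg.n_nodes() == 4  # repeat node + three unique segments

    def test_repeat_free_circular_degenerates_to_single_node(self):
        rng = np.random.default_rng(8)
        g = Genome("t", random_sequence(rng, 400), circular=True)
        sg = simplify(build_graph(g, 15))
        assert sg.n_nodes() == 1 and sg.n_edge_instances() == 0

    def test_no_collapse_flag_keeps_decision_node(self, single_repeat_genome):
        sg = simplify(build_graph(single_repeat_genome, 50), collapse=False)
        assert len(sg.decision_nodes()) == 1
        assert enumerate_eulerian(sg) == enumerate_eulerian(
            build_graph(single_repeat_genome, 50))


class TestSimplify:
    def test_fixpoint(self, bubble_graph):
        again = simplify(bubble_graph)
        assert {again.label(n) for n in again.nodes()} == {
            bubble_graph.label(n) for n in bubble_graph.nodes()}

    def test_structure_postcondition(self, bubble_graph, array_graph):
        # every node is a decision node or sandwiched between repeats with
        # in = out = 1 distinct neighbor and no mergeable link remains
        for kg in (bubble_graph, array_graph):
            for n in kg.nodes():
                if kg.is_decision(n):
                    continue
                assert len(kg.predecessors(n)) == 1
                assert len(kg.successors(n)) == 1
                (s,) = kg.successors(n)
                assert kg.is_decision(s) or set(kg.g.predecessors(s)) != {n}

    def test_genome_remains_a_traversal(self, bubble_genome, bubble_graph):
        G = len(bubble_genome)
        spellings = enumerate_eulerian(bubble_graph, cap=64)
        seq = bubble_genome.sequence
        canonical = min((seq + seq)[i : i + G] for i in range(G))
        assert canonical in spellings

    def test_occurrence_annotation_survives_simplification(self, bubble_genome, bubble_graph):
        bubble_graph.validate(bubble_genome)

    @pytest.mark.parametrize("seed", range(40, 52))
    def test_losslessness_random_plans(self, seed):
        plan = random_plan(seed)
        g = generate_genome(plan)
        for k in (11, 15, 21):
            kg = build_graph(g, k)
            try:
                pre = enumerate_eulerian(kg, cap=256)
            except Exception:
                continue  # too tangled for the oracle at this k
            sg = simplify(kg)
            assert enumerate_eulerian(sg, cap=256) == pre
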