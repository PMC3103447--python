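"""Unique-shortest-path classification and repeat resolution."""

import itertools

import pytest

from matetune import (
    LibrarySpec,
    MatePair,
    MatePairCategory,
    PathOracle,
    apply_resolutions,
    build_graph,
    classify_matepair,
    experiment_stats,
    place_ends,
    sample_matepairs,
    shortest_separation,
    simplify,
    spell_path,
)


def brute_force_separations(kg, n1, n2, max_edges=10):
    """All path-weight sums n1 -> n2 by exhaustive walk enumeration (with
    revisits) up to max_edges edges; independent of the Dijkstra/DAG code."""
    w = {n: len(kg.label(n)) - kg.overlap for n in kg.nodes()}
    results = {}  # total -> set of node paths
    stack = [(n1, (n1,), 0)]
    while stack:
        node, path, total = stack.pop()
        if node == n2 and len(path) > 1:
            results.setdefault(total, set()).add(path)
        if len(path) > max_edges:
            continue
        for v in set(kg.g.successors(node)):
            stack.append((v, path + (v,), total + w[node]))
    return results


class TestShortestSeparation:
    def test_same_node_direct(self, array_graph):
        from matetune.graph import Placement
        n = array_graph.nodes()[0]
        r = shortest_separation(array_graph,
                                Placement(n, 5, 0), Placement(n, 42, 0))
        assert (r.separation, r.n_paths, r.path) == (37, 1, (n,))

    def test_agrees_with_exhaustive_enumeration(self, bubble_graph, array_graph):
        for kg in (bubble_graph, array_graph):
            oracle = PathOracle(kg)
            for n1, n2 in itertools.permutations(kg.nodes(), 2):
                res = oracle.query(n1, n2)
                brute = brute_force_separations(kg, n1, n2)
                if not brute:
                    assert res.separation is None
                    continue
                best = min(brute)
                assert res.separation == best
                assert res.n_paths == min(len(brute[best]), oracle.cap + 1)
                if res.n_paths == 1:
                    assert {res.path} == brute[best]

    def test_separation_equals_genomic_distance(self, bubble_genome, bubble_graph):
        # a usable pair's D* reproduces the true separation between reads
        lib = LibrarySpec(mean_insert=255, read_length=35, n_pairs=800)
        oracle = PathOracle(bubble_graph)
        checked = 0
        for mp in sample_matepairs(bubble_genome, lib, seed=3):
            cp = classify_matepair(bubble_graph, bubble_genome, mp, oracle)
            if cp.category is MatePairCategory.USABLE:
                assert cp.separation == mp.insert - 35
                checked += 1
        assert checked > 10


class TestClassification:
    def test_same_node(self, array_genome, array_graph):
        mp = MatePair(start=10_000, insert=400, read_length=35)
        cp = classify_matepair(array_graph, array_genome, mp)
        assert cp.category is MatePairCategory.SAME_NODE
        assert not cp.cross_fork

    def test_adjacent(self, array_genome, array_graph):
        # read1 just before the first repeat copy, read2 inside it
        first = min(c.start for c in array_genome.planted)
        mp = MatePair(start=first - 50, insert=135, read_length=35)
        cp = classify_matepair(array_graph, array_genome, mp)
        assert cp.category is MatePairCategory.ADJACENT

    def test_usable_spans_one_copy(self, array_genome, array_graph):
        # tight pair across a single repeat copy with distinct flanks
        copies = sorted(c.start for c in array_genome.planted)
        start = copies[1] - 60  # in spacer 1, 60 nt before copy 2
        insert = 60 + 200 + 80  # lands 45 nt into spacer 2
        mp = MatePair(start=start, insert=insert, read_length=35)
        cp = classify_matepair(array_graph, array_genome, mp)
        assert cp.category is MatePairCategory.USABLE
        assert cp.seq_match and cp.len_match and cp.unique

    def test_ambiguous_across_bubble(self, bubble_genome, bubble_graph):
        # reads flanking both bubble repeats: two equal-length minimal paths
        copies = sorted(bubble_genome.planted, key=lambda c: c.start)
        start = copies[0].start - 100          # before the first R1
        insert = 100 + 150 + 300 + 150 + 135   # beyond the first R2
        mp = MatePair(start=start, insert=insert, read_length=35)
        cp = classify_matepair(bubble_graph, bubble_genome, mp)
        assert cp.category is MatePairCategory.AMBIGUOUS
        assert cp.len_match  # both paths have the true length

    def test_no_exact_match_when_shortcut_exists(self, array_genome, array_graph):
        # pair spanning two copies: the direct path through the repeat is
        # shorter than the true two-copy traversal
        copies = sorted(c.start for c in array_genome.planted)
        start = copies[1] - 60
        insert = 60 + 200 + 300 + 200 + 80
        mp = MatePair(start=start, insert=insert, read_length=35)
        cp = classify_matepair(array_graph, array_genome, mp)
        assert cp.category is MatePairCategory.NO_EXACT_MATCH
        assert not cp.len_match


class TestApplyResolutions:
    def collect_usable(self, genome, kg, insert, n=4000, seed=9):
        oracle = PathOracle(kg)
        lib = LibrarySpec(mean_insert=insert, read_length=kg.k, n_pairs=n)
        out = [classify_matepair(kg, genome, mp, oracle)
               for mp in sample_matepairs(genome, lib, seed)]
        return [c for c in out if c.category is MatePairCategory.USABLE], out

    def test_no_usable_pairs_keeps_complexity(self, array_graph):
        outcome = apply_resolutions(array_graph, [])
        assert outcome.residual_complexity == outcome.original_complexity == 6
        assert outcome.reduction_percent == 0.0

    def test_tuned_library_fully_resolves_array(self, array_genome, array_graph):
        usable, _ = self.collect_usable(array_genome, array_graph, 305)
        outcome = apply_resolutions(array_graph, usable)
        assert outcome.reduction_percent == 100.0
        (node,) = array_graph.decision_nodes()
        assert len(outcome.per_node[node].accepted) >= 3

    def test_monotonicity(self, array_genome, array_graph):
        usable, _ = self.collect_usable(array_genome, array_graph, 305)
        residuals = []
        for i in (0, len(usable) // 4, len(usable) // 2, len(usable)):
            residuals.append(apply_resolutions(array_graph, usable[:i]).residual_complexity)
        assert residuals == sorted(residuals, reverse=True)

    def test_degree_reduction_arithmetic(self, array_genome, array_graph):
        usable, _ = self.collect_usable(array_genome, array_graph, 305)
        (node,) = array_graph.decision_nodes()
        one = [u for u in usable if node in (u.path or ())][:1]
        outcome = apply_resolutions(array_graph, one)
        nr = outcome.per_node[node]
        assert len(nr.accepted) == 1
        assert nr.residual_degree == 3
        assert nr.residual_complexity == 3


class TestExperimentStats:
    def test_percentages(self, array_genome, array_graph):
        oracle = PathOracle(array_graph)
        lib = LibrarySpec(mean_insert=305, read_length=35, n_pairs=3000)
        classified = [classify_matepair(array_graph, array_genome, mp, oracle)
                      for mp in sample_matepairs(array_genome, lib, seed=21)]
        usable = [c for c in classified if c.category is MatePairCategory.USABLE]
        stats = experiment_stats(classified, apply_resolutions(array_graph, usable))
        assert stats.usable <= stats.cross_fork
        assert 0 <= stats.usable <= 100 and 0 <= stats.path_len_match <= 100
        assert stats.compl_reduc == 100.0
        assert stats.n_pairs == 3000

    def test_empty_classified_rejected(self):
        with pytest.raises(ValueError):
            experiment_stats([], None)
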