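"""Repeat resolution with mate-pairs via the unique-shortest-path heuristic.

A mate-pair is *usable* for repeat resolution when its reads place in two
distinct, non-adjacent nodes connected by exactly one shortest path whose
length is exactly consistent with the known insert (the expected
separation between read starts is d - k).  Usable pairs pin down, at every
decision node interior to their path, which entering neighbor pairs with
which leaving neighbor; accumulating these pairings reduces the residual
finishing complexity of the graph.

Path lengths count node labels minus the k-2 letter overlaps between
consecutive nodes, so the minimal separation D* equals genomic separation
along the spelled path.  Uniqueness is judged over node sequences: parallel
edge instances spell identically and do not create distinct paths.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from enum import Enum

from .genomes import Genome
from .graph import KmerGraph, Placement, spell_path
from .matepairs import MatePair, place_ends
from .complexity import node_finishing_complexity, graph_finishing_complexity

__all__ = [
    "MatePairCategory",
    "PathResult",
    "ClassifiedPair",
    "PathOracle",
    "shortest_separation",
    "classify_matepair",
    "apply_resolutions",
    "experiment_stats",
    "ResolutionOutcome",
    "ExperimentStats",
]

DEFAULT_PATH_COUNT_CAP = 16


class MatePairCategory(str, Enum):
    SAME_NODE = "SAME_NODE"
    ADJACENT = "ADJACENT"
    NO_EXACT_MATCH = "NO_EXACT_MATCH"
    AMBIGUOUS = "AMBIGUOUS"
    USABLE = "USABLE"


@dataclass(frozen=True)
class PathResult:
    """Minimal separation between two placements and path multiplicity."""

    separation: int | None        # D*; None if unreachable
    n_paths: int                  # distinct minimal node-paths (capped)
    path: tuple[int, ...] | None  # the unique minimal path when n_paths == 1


@dataclass(frozen=True)
class ClassifiedPair:
    pair: MatePair
    p1: Placement
    p2: Placement
    category: MatePairCategory
    len_match: bool
    cross_fork: bool
    unique: bool
    seq_match: bool
    separation: int | None
    path: tuple[int, ...] | None


class PathOracle:
    """Cached single-source shortest-path queries on a simplified graph.

    Distances use the node-weight w(u) = len(label(u)) - (k-2); minimal-path
    multiplicity is counted on the shortest-path DAG and capped (uniqueness
    only requires distinguishing 1 from >1).
    """

    def __init__(self, kg: KmerGraph, cap: int = DEFAULT_PATH_COUNT_CAP):
        self.kg = kg
        self.cap = cap
        self._succ: dict[int, list[int]] = {
            n: sorted(set(kg.g.successors(n))) for n in kg.g.nodes
        }
        self._w = {n: len(kg.label(n)) - kg.overlap for n in kg.g.nodes}
        self._cache: dict[int, tuple[dict, dict, dict]] = {}
        self._counters: dict[int, object] = {}

    def _run(self, src: int):
        if src in self._cache:
            return self._cache[src]
        dist: dict[int, int] = {src: 0}
        heap = [(0, src)]
        done = set()
        while heap:
            d, u = heapq.heappop(heap)
            if u in done:
                continue
            done.add(u)
            du = d + self._w[u]
            for v in self._succ[u]:
                if v not in dist or du < dist[v]:
                    dist[v] = du
                    heapq.heappush(heap, (du, v))
        # shortest-path DAG predecessor lists and capped path counts
        preds: dict[int, list[int]] = {n: [] for n in dist}
        for u in dist:
            du = dist[u] + self._w[u]
            for v in self._succ[u]:
                if v in dist and dist[v] == du:
                    preds[v].append(u)
        counts: dict[int, int] = {}

        def count(v: int) -> int:
            if v == src:
                return 1
            if v not in counts:
                c = 0
                for u in preds[v]:
                    c += count(u)
                    if c > self.cap:
                        break
                counts[v] = min(c, self.cap + 1)
            return counts[v]

        self._cache[src] = (dist, preds, counts)
        self._counters[src] = count
        return self._cache[src]

    def query(self, n1: int, n2: int) -> PathResult:
        """Minimal path-weight sum from n1 to n2 (0 if n1 == n2) plus the
        number of minimal node-paths and, if unique, the path itself."""
        dist, preds, _ = self._run(n1)
        if n2 not in dist:
            return PathResult(None, 0, None)
        count = self._counters[n1]
        c = count(n2)
        path = None
        if c == 1:
            path = [n2]
            while path[-1] != n1:
                path.append(preds[path[-1]][0])
            path = tuple(reversed(path))
        return PathResult(dist[n2], min(c, self.cap + 1), path)

    def query_cycle(self, n: int) -> PathResult:
        """Minimal closed-walk weight n -> n using at least one edge."""
        dist, preds, _ = self._run(n)
        best = None
        for u in self.kg.predecessors(n):
            if u in dist:
                d = dist[u] + self._w[u]
                if best is None or d < best:
                    best = d
        if best is None:
            return PathResult(None, 0, None)
        count = self._counters[n]
        c = sum(count(u) for u in self.kg.predecessors(n)
                if u in dist and dist[u] + self._w[u] == best)
        return PathResult(best, min(c, self.cap + 1), None)


def shortest_separation(kg: KmerGraph, p1: Placement, p2: Placement,
                        oracle: PathOracle | None = None,
                        cap: int = DEFAULT_PATH_COUNT_CAP) -> PathResult:
    """Minimal separation D* between two read placements.

    D* minimizes sum(len(v_j) - (k-2)) over interior path nodes plus the
    offset difference, which equals genomic separation along the spelled
    path.  Both placements on one node with offset2 >= offset1 give the
    within-node separation directly.
    """
    oracle = oracle or PathOracle(kg, cap)
    if p1.node == p2.node and p2.offset >= p1.offset:
        return PathResult(p2.offset - p1.offset, 1, (p1.node,))
    if p1.node == p2.node:
        r = oracle.query_cycle(p1.node)
    else:
        r = oracle.query(p1.node, p2.node)
    if r.separation is None:
        return r
    return PathResult(r.separation + p2.offset - p1.offset, r.n_paths, r.path)


def _sequence_matches(kg: KmerGraph, genome: Genome, mp: MatePair,
                      p1: Placement, path: tuple[int, ...], dstar: int) -> bool:
    """Does the unique shortest path spell the genomic substring [s, s+d)?

    Compares the spelled path from read1's offset against the genome; the
    final character may fall one node past the path end when read2
    straddles a junction, in which case the comparison stops one letter
    short (the straddling letter lives on the next node's edge).
    """
    spelled = spell_path(kg, path)
    span = dstar + mp.read_length
    avail = len(spelled) - p1.offset
    n = min(span, avail)
    if n < span - 1:
        return False
    return spelled[p1.offset : p1.offset + n] == genome.substring(mp.start, n)


def classify_matepair(kg: KmerGraph, genome: Genome, mp: MatePair,
                      oracle: PathOracle | None = None,
                      cap: int = DEFAULT_PATH_COUNT_CAP) -> ClassifiedPair:
    """Classify one mate-pair for repeat resolution.

    SAME_NODE and ADJACENT pairs carry no repeat-spanning information;
    remaining pairs are AMBIGUOUS (several minimal paths), NO_EXACT_MATCH
    (minimal separation disagrees with the known insert, or unreachable) or
    USABLE.
    """
    oracle = oracle or PathOracle(kg, cap)
    p1, p2 = place_ends(kg, mp)
    expected = mp.insert - mp.read_length
    res = shortest_separation(kg, p1, p2, oracle)
    len_match = res.separation == expected
    if p1.node == p2.node:
        return ClassifiedPair(mp, p1, p2, MatePairCategory.SAME_NODE,
                              len_match, False, res.n_paths == 1, False,
                              res.separation, res.path)
    adjacent = kg.g.has_edge(p1.node, p2.node)
    if adjacent:
        return ClassifiedPair(mp, p1, p2, MatePairCategory.ADJACENT,
                              len_match, False, res.n_paths == 1, False,
                              res.separation, res.path)
    unique = res.n_paths == 1
    seq_match = bool(
        unique and res.path and _sequence_matches(kg, genome, mp, p1, res.path, res.separation)
    )
    if res.separation is None or res.n_paths == 0:
        cat = MatePairCategory.NO_EXACT_MATCH
    elif not unique:
        cat = MatePairCategory.AMBIGUOUS
    elif not len_match:
        cat = MatePairCategory.NO_EXACT_MATCH
    else:
        cat = MatePairCategory.USABLE
    return ClassifiedPair(mp, p1, p2, cat, len_match, True, unique, seq_match,
                          res.separation, res.path)


# ---------------------------------------------------------------------------
# applying usable pairs
# ---------------------------------------------------------------------------


@dataclass
class NodeResolution:
    node: int
    degree: int
    support: dict[tuple[int, int], int] = field(default_factory=dict)
    accepted: list[tuple[int, int]] = field(default_factory=list)
    residual_degree: int = 0
    residual_complexity: int = 0


@dataclass
class ResolutionOutcome:
    per_node: dict[int, NodeResolution]
    original_complexity: int
    residual_complexity: int

    @property
    def reduction_percent(self) -> float:
        if self.original_complexity == 0:
            return 0.0
        return 100.0 * (self.original_complexity - self.residual_complexity) / self.original_complexity


def apply_resolutions(kg: KmerGraph, usable: list[ClassifiedPair]) -> ResolutionOutcome:
    """Accumulate edge pairings implied by usable pairs and reduce degrees.

    Every decision node interior to a usable pair's unique path receives a
    (entering-neighbor, leaving-neighbor) pairing.  Pairings are accepted in
    decreasing support order subject to slot capacities (edge-instance
    counts per neighbor); pairings tied in support that compete for the
    same slot are discarded.  A node with r accepted pairings retains
    residual complexity C(max(a - r, 0)) with C(x) = x(x-1)/2.
    """
    support: dict[int, dict[tuple[int, int], int]] = {}
    for cp in usable:
        if cp.category != MatePairCategory.USABLE or not cp.path:
            raise ValueError("apply_resolutions expects USABLE pairs with unique paths")
        path = cp.path
        for j in range(1, len(path) - 1):
            v = path[j]
            if kg.is_decision(v):
                key = (path[j - 1], path[j + 1])
                support.setdefault(v, {})[key] = support.setdefault(v, {}).get(key, 0) + 1

    per_node: dict[int, NodeResolution] = {}
    original = graph_finishing_complexity(kg)
    residual_total = 0
    for n in kg.g.nodes:
        a = kg.degree(n)
        nr = NodeResolution(node=n, degree=a)
        pairings = support.get(n, {})
        nr.support = dict(pairings)
        in_cap: dict[int, int] = {}
        out_cap: dict[int, int] = {}
        for u, _ in kg.g.in_edges(n):
            in_cap[u] = in_cap.get(u, 0) + 1
        for _, w in kg.g.out_edges(n):
            out_cap[w] = out_cap.get(w, 0) + 1
        by_level: dict[int, list[tuple[int, int]]] = {}
        for key, s in pairings.items():
            by_level.setdefault(s, []).append(key)
        for level in sorted(by_level, reverse=True):
            cands = sorted(by_level[level])
            in_demand: dict[int, int] = {}
            out_demand: dict[int, int] = {}
            for u, w in cands:
                in_demand[u] = in_demand.get(u, 0) + 1
                out_demand[w] = out_demand.get(w, 0) + 1
            for u, w in cands:
                if in_demand[u] > in_cap.get(u, 0) or out_demand[w] > out_cap.get(w, 0):
                    continue  # competing ties (or exhausted slots) are dropped
                nr.accepted.append((u, w))
                in_cap[u] -= 1
                out_cap[w] -= 1
        r = len(nr.accepted)
        nr.residual_degree = max(a - r, 0)
        nr.residual_complexity = node_finishing_complexity(nr.residual_degree)
        residual_total += nr.residual_complexity
        per_node[n] = nr
    return ResolutionOutcome(per_node, original, residual_total)


# ---------------------------------------------------------------------------
# experiment statistics (Table-2 vocabulary)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentStats:
    """The six headline percentages of a resolution experiment.

    PathLenMatch, CrossFork and Usable are fractions of all pairs;
    Unique is the fraction of cross-fork pairs with a unique minimal path;
    MatchSeq is the fraction of cross-fork pairs with a unique minimal path
    whose spelling is the true genomic substring.
    """

    path_len_match: float
    cross_fork: float
    match_seq: float
    unique: float
    usable: float
    compl_reduc: float
    n_pairs: int
    zero_complexity: bool = False

    def as_dict(self) -> dict:
        return {
            "PathLenMatch": self.path_len_match,
            "CrossFork": self.cross_fork,
            "MatchSeq": self.match_seq,
            "Unique": self.unique,
            "Usable": self.usable,
            "ComplReduc": self.compl_reduc,
            "n_pairs": self.n_pairs,
        }


def experiment_stats(classified: list[ClassifiedPair], outcome: ResolutionOutcome) -> ExperimentStats:
    if not classified:
        raise ValueError("no classified pairs")
    n = len(classified)
    cross = [c for c in classified if c.cross_fork]
    n_cross = len(cross)
    n_cross_unique = sum(1 for c in cross if c.unique)
    return ExperimentStats(
        path_len_match=100.0 * sum(1 for c in classified if c.len_match) / n,
        cross_fork=100.0 * n_cross / n,
        match_seq=100.0 * sum(1 for c in cross if c.seq_match) / n_cross if n_cross else 0.0,
        unique=100.0 * n_cross_unique / n_cross if n_cross else 0.0,
        usable=100.0 * sum(1 for c in classified if c.category == MatePairCategory.USABLE) / n,
        compl_reduc=outcome.reduction_percent,
        n_pairs=n,
        zero_complexity=outcome.original_complexity == 0,
    )
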