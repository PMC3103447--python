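"""Idealized de Bruijn repeat graphs with genome-coordinate annotation.

A graph of order ``k`` has one node per distinct (k-1)-mer present in the
genome and one directed edge *instance* per k-mer occurrence (repeated
k-mers contribute parallel edges).  Because nodes are shared between repeat
copies, a genomic repeat appears as a single node traversed several times;
the genome itself is one Eulerian traversal of the graph.

Conventions used throughout the package:

* coordinates are 0-based, half-open, forward strand;
* circular genomes wrap around the origin, so a circular genome of length G
  contributes exactly G edge instances;
* adjacent node labels along an edge overlap by exactly ``k - 2`` letters
  (two consecutive (k-1)-mers share k-2 letters; the property is preserved
  by all simplification transforms);
* every node records the sorted genome start coordinates of its
  occurrences, and every edge instance records the start coordinate of the
  k-mer spanning its junction.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .genomes import Genome

__all__ = [
    "KmerGraph",
    "Placement",
    "build_graph",
    "spell_path",
    "enumerate_eulerian",
    "TooComplexError",
    "write_gfa",
    "read_gfa",
]


class TooComplexError(RuntimeError):
    """The brute-force traversal oracle exceeded its enumeration cap."""


@dataclass(frozen=True)
class Placement:
    """A read located on a node of the (simplified) graph."""

    node: int
    offset: int       # within the node label
    coord: int        # genome coordinate the placement realizes


class KmerGraph:
    """Annotated directed multigraph over (k-1)-mer derived nodes.

    Thin wrapper around :class:`networkx.MultiDiGraph`.  Node attributes:
    ``label`` (DNA string) and ``occ`` (sorted genome start coordinates).
    Edge attribute: ``coord`` (start of the junction k-mer instance).
    """

    def __init__(self, k: int, genome_length: int, circular: bool, genome_id: str = ""):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.k = k
        self.genome_length = genome_length
        self.circular = circular
        self.genome_id = genome_id
        self.g = nx.MultiDiGraph()
        self._next_id = 0
        self.collapse_incomplete = False  # set if a unique-tour test hit its cap
        self._index: tuple[list[int], list[int]] | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def overlap(self) -> int:
        """Letters shared between adjacent node labels (= k - 2)."""
        return self.k - 2

    def new_node(self, label: str, occ: Iterable[int]) -> int:
        nid = self._next_id
        self._next_id += 1
        self.g.add_node(nid, label=label, occ=sorted(occ))
        self._index = None
        return nid

    def label(self, n: int) -> str:
        return self.g.nodes[n]["label"]

    def occ(self, n: int) -> list[int]:
        return self.g.nodes[n]["occ"]

    def nodes(self) -> list[int]:
        return list(self.g.nodes)

    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    def n_edge_instances(self) -> int:
        return self.g.number_of_edges()

    def in_deg(self, n: int) -> int:
        return self.g.in_degree(n)

    def out_deg(self, n: int) -> int:
        return self.g.out_degree(n)

    def degree(self, n: int) -> int:
        """Repeat degree a: in- and out-instance counts coincide on balanced
        graphs; the max covers linear-genome end nodes."""
        return max(self.in_deg(n), self.out_deg(n))

    def predecessors(self, n: int) -> set[int]:
        return set(self.g.predecessors(n))

    def successors(self, n: int) -> set[int]:
        return set(self.g.successors(n))

    def is_decision(self, n: int) -> bool:
        return self.in_deg(n) >= 2 and self.out_deg(n) >= 2

    def decision_nodes(self) -> list[int]:
        return [n for n in self.g.nodes if self.is_decision(n)]

    def is_balanced(self) -> bool:
        return all(self.in_deg(n) == self.out_deg(n) for n in self.g.nodes)

    def copy(self) -> "KmerGraph":
        other = KmerGraph(self.k, self.genome_length, self.circular, self.genome_id)
        other.g = self.g.copy()
        other._next_id = self._next_id
        other.collapse_incomplete = self.collapse_incomplete
        return other

    # -- coordinate lookup ---------------------------------------------------

    def _build_index(self) -> tuple[list[int], list[int]]:
        pairs = sorted((o, n) for n in self.g.nodes for o in self.occ(n))
        starts = [p[0] for p in pairs]
        nodes = [p[1] for p in pairs]
        return starts, nodes

    def locate(self, coord: int) -> Placement:
        """Map a genome coordinate to the node occurrence whose core contains
        it (the occurrence with the largest start <= coord, wrapping on
        circular genomes)."""
        if self._index is None:
            self._index = self._build_index()
        starts, nodes = self._index
        if not starts:
            raise ValueError("empty graph")
        G = self.genome_length
        c = coord % G if self.circular else coord
        i = bisect.bisect_right(starts, c) - 1
        if i < 0:
            if not self.circular:
                raise ValueError(f"coordinate {coord} precedes all occurrences")
            i = len(starts) - 1  # wraps to the occurrence spanning the origin
        start, node = starts[i], nodes[i]
        offset = (c - start) % G if self.circular else c - start
        return Placement(node, offset, c)

    # -- spelling ------------------------------------------------------------

    def spell_path(self, path: Sequence[int]) -> str:
        return spell_path(self, path)

    def validate(self, genome: Genome | None = None) -> None:
        """Check structural invariants; with the source genome, also check
        occurrence/label consistency and edge-coordinate bookkeeping."""
        o = self.overlap
        for u, v in set(self.g.edges()):
            lu, lv = self.label(u), self.label(v)
            if lu[len(lu) - o:] != lv[:o]:
                raise AssertionError(f"labels of {u}->{v} do not overlap by {o}")
        if genome is not None:
            for n in self.g.nodes:
                lab = self.label(n)
                for occ in self.occ(n):
                    if genome.substring(occ, len(lab)) != lab:
                        raise AssertionError(f"occurrence {occ} of node {n} mismatches label")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def build_graph(genome: Genome, k: int) -> KmerGraph:
    """Build the order-k de Bruijn graph of ``genome``.

    One node per distinct (k-1)-mer, one edge instance per k-mer occurrence
    carrying its genome coordinate.  Circular genomes wrap (G edge
    instances); linear genomes yield G - k + 1 instances.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    G = len(genome)
    if G < k:
        raise ValueError(f"genome length {G} < k = {k}")
    seq = genome.sequence + (genome.sequence[: k - 1] if genome.circular else "")
    n_kmers = G if genome.circular else G - k + 1
    n_nodes = G if genome.circular else G - k + 2

    kg = KmerGraph(k, G, genome.circular, genome.id)
    ids: dict[str, int] = {}
    occ: dict[int, list[int]] = {}
    node_at: list[int] = []
    for i in range(n_nodes):
        mer = seq[i : i + k - 1]
        nid = ids.get(mer)
        if nid is None:
            nid = kg._next_id
            kg._next_id += 1
            ids[mer] = nid
            occ[nid] = []
            kg.g.add_node(nid, label=mer)
        occ[nid].append(i % G)
        node_at.append(nid)
    for nid, positions in occ.items():
        kg.g.nodes[nid]["occ"] = sorted(set(positions))
    for i in range(n_kmers):
        u = node_at[i]
        v = node_at[(i + 1) % G] if genome.circular else node_at[i + 1]
        kg.g.add_edge(u, v, coord=i)
    return kg


def spell_path(graph: KmerGraph, path: Sequence[int]) -> str:
    """Spell the DNA string of a node path (labels overlapping by k-2)."""
    if not path:
        raise ValueError("empty path")
    o = graph.overlap
    pieces = [graph.label(path[0])]
    for u, v in zip(path, path[1:]):
        if not graph.g.has_edge(u, v):
            raise ValueError(f"no edge {u}->{v}")
        pieces.append(graph.label(v)[o:])
    return "".join(pieces)


# ---------------------------------------------------------------------------
# brute-force traversal oracle
# ---------------------------------------------------------------------------


def _canonical_rotation(s: str) -> str:
    if not s:
        return s
    d = s + s
    return min(d[i : i + len(s)] for i in range(len(s)))


def _circuit_spelling(graph: KmerGraph, nodes: Sequence[int]) -> str:
    """Cyclic sequence spelled by an Eulerian circuit (node walk returning to
    its start), canonicalized by lexicographically minimal rotation."""
    o = graph.overlap
    length = sum(len(graph.label(n)) - o for n in nodes[:-1])
    return _canonical_rotation(spell_path(graph, nodes)[:length])


def iter_eulerian_walks(succs: dict[int, list[int]], mult: dict[tuple[int, int], int],
                        start: int, total_edges: int, cap: int,
                        max_steps: int = 2_000_000) -> list[tuple[int, ...]] | None:
    """All edge-exhausting walks from ``start``, by iterative backtracking.

    Parallel edge instances between one node pair are interchangeable (they
    spell identically), so multiplicities rather than edge identities are
    tracked.  Returns None once more than ``cap`` complete walks are found
    or the exploration step budget is exceeded.  ``mult`` is restored on
    return.
    """
    walks: list[tuple[int, ...]] = []
    walk = [start]
    iters = [iter(succs.get(start, ()))]
    used = 0
    steps = 0

    def backstep() -> bool:
        nonlocal used
        iters.pop()
        if not iters:
            return False
        v = walk.pop()
        mult[(walk[-1], v)] += 1
        used -= 1
        return True

    while iters:
        steps += 1
        if steps > max_steps:
            _unwind(walk, mult)
            return None
        if used == total_edges:
            walks.append(tuple(walk))
            if len(walks) > cap:
                _unwind(walk, mult)
                return None
            if not backstep():
                break
            continue
        advanced = False
        for v in iters[-1]:
            if mult[(walk[-1], v)] > 0:
                mult[(walk[-1], v)] -= 1
                used += 1
                walk.append(v)
                iters.append(iter(succs.get(v, ())))
                advanced = True
                break
        if not advanced and not backstep():
            break
    return walks


def _unwind(walk: list[int], mult: dict[tuple[int, int], int]) -> None:
    while len(walk) > 1:
        v = walk.pop()
        mult[(walk[-1], v)] += 1


def _edge_multiset(edges) -> tuple[dict[int, list[int]], dict[tuple[int, int], int]]:
    mult: dict[tuple[int, int], int] = {}
    for u, v in edges:
        mult[(u, v)] = mult.get((u, v), 0) + 1
    succs: dict[int, list[int]] = {}
    for u, v in mult:
        succs.setdefault(u, []).append(v)
    for u in succs:
        succs[u].sort()
    return succs, mult


def enumerate_eulerian(graph: KmerGraph, cap: int = 1024,
                       max_steps: int = 2_000_000) -> set[str]:
    """Exact set of spellings of all Eulerian traversals.

    Balanced graphs are traversed as circuits; spellings of circuits are
    canonicalized by minimal rotation (a circuit has no distinguished
    start).  Unbalanced graphs are traversed as paths from the unique
    unbalanced start node.  Raises :class:`TooComplexError` once more than
    ``cap`` completed traversals have been enumerated or the exploration
    budget is exhausted.
    """
    g = graph.g
    if g.number_of_nodes() == 0:
        return set()
    if g.number_of_edges() == 0:
        if g.number_of_nodes() > 1:
            raise ValueError("edgeless graph with several nodes has no traversal")
        n = next(iter(g.nodes))
        lab = graph.label(n)
        if graph.circular:
            return {_canonical_rotation(lab[: len(lab) - graph.overlap])}
        return {lab}

    balanced = graph.is_balanced()
    if balanced:
        start = min(n for n in g.nodes if g.degree(n) > 0)
    else:
        starts = [n for n in g.nodes if g.out_degree(n) - g.in_degree(n) == 1]
        ends = [n for n in g.nodes if g.in_degree(n) - g.out_degree(n) == 1]
        if len(starts) != 1 or len(ends) != 1:
            raise ValueError("graph is neither balanced nor unicursal")
        start = starts[0]

    succs, mult = _edge_multiset(g.edges())
    walks = iter_eulerian_walks(succs, mult, start, g.number_of_edges(), cap, max_steps)
    if walks is None:
        raise TooComplexError(f"more than {cap} Eulerian traversals (or budget hit)")
    spellings: set[str] = set()
    for walk in walks:
        if balanced:
            if walk[-1] == walk[0]:
                spellings.add(_circuit_spelling(graph, walk))
        else:
            spellings.add(spell_path(graph, walk))
    return spellings


# ---------------------------------------------------------------------------
# serialization (GFA-like dialect, version 1)
# ---------------------------------------------------------------------------


def write_gfa(graph: KmerGraph, path: str | Path, occurrences: str | Path | None = None) -> None:
    """Write the graph as GFA-like text (S/L lines, overlap k-2) plus an
    optional sidecar TSV of node occurrences."""
    o = graph.overlap
    with open(path, "w") as fh:
        fh.write(f"H\tVN:Z:matetune-1\tKM:i:{graph.k}\tGL:i:{graph.genome_length}"
                 f"\tCR:i:{int(graph.circular)}\tID:Z:{graph.genome_id or '.'}\n")
        for n in sorted(graph.g.nodes):
            fh.write(f"S\t{n}\t{graph.label(n)}\n")
        for u, v, data in sorted(graph.g.edges(data=True), key=lambda e: (e[0], e[1], e[2].get("coord", -1))):
            fh.write(f"L\t{u}\t+\t{v}\t+\t{o}M\tCO:i:{data.get('coord', -1)}\n")
    if occurrences is not None:
        with open(occurrences, "w") as fh:
            fh.write("node\tstart\n")
            for n in sorted(graph.g.nodes):
                for s in graph.occ(n):
                    fh.write(f"{n}\t{s}\n")


def read_gfa(path: str | Path, occurrences: str | Path | None = None) -> KmerGraph:
    """Read a graph written by :func:`write_gfa`."""
    kg: KmerGraph | None = None
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "H":
                tags = dict(p.split(":", 2)[::2] for p in parts[1:])
                kg = KmerGraph(int(tags["KM"]), int(tags["GL"]), bool(int(tags["CR"])),
                               "" if tags.get("ID") == "." else tags.get("ID", ""))
            elif parts[0] == "S":
                assert kg is not None
                nid = int(parts[1])
                kg.g.add_node(nid, label=parts[2], occ=[])
                kg._next_id = max(kg._next_id, nid + 1)
            elif parts[0] == "L":
                assert kg is not None
                coord = -1
                for tag in parts[6:]:
                    if tag.startswith("CO:i:"):
                        coord = int(tag[5:])
                kg.g.add_edge(int(parts[1]), int(parts[3]), coord=coord)
    if kg is None:
        raise ValueError(f"{path}: missing header")
    if occurrences is not None:
        with open(occurrences) as fh:
            next(fh)
            for line in fh:
                n, s = line.split()
                kg.g.nodes[int(n)]["occ"].append(int(s))
        for n in kg.g.nodes:
            kg.g.nodes[n]["occ"].sort()
    return kg
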