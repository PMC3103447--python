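"""Lossless simplification of de Bruijn repeat graphs.

Three transformations reduce the raw k-mer graph to a compact repeat graph
without changing its set of Eulerian-traversal spellings:

1. **Path compression** — if ``u`` is the only predecessor of ``v`` and
   ``v`` the only successor of ``u`` (one edge instance each way), the two
   nodes merge into one whose label concatenates theirs minus the k-2
   overlap.

2. **Unique-tour collapse** — a region whose cycle decomposition is a tree
   admits exactly one Eulerian tour and is replaced by a single node
   spelling that tour.  Detection here is semantic: candidate regions are
   tested by bounded brute-force enumeration of their traversal spellings
   (regions exceeding the cap are left alone, which is lossless but less
   compact, and flagged on the graph).

3. **Unzipping** — a half-decision node (one distinct predecessor but
   several successors, or the mirror) is duplicated per branch; genome
   coordinates decide which occurrence follows which branch, and the
   resulting unambiguous paths are compressed.

After :func:`simplify` every node is either a decision node (in = out >= 2
edge instances) or a non-decision node sandwiched between repeats.
"""

from __future__ import annotations

import networkx as nx

from .graph import (
    KmerGraph,
    TooComplexError,
    _edge_multiset,
    iter_eulerian_walks,
    spell_path,
)

__all__ = [
    "compress_unambiguous_paths",
    "unzip_half_decision_nodes",
    "collapse_unique_tour_components",
    "simplify",
]

MAX_FIXPOINT_ROUNDS = 100


# ---------------------------------------------------------------------------
# 1. path compression
# ---------------------------------------------------------------------------


def _chains(kg: KmerGraph) -> list[list[int]]:
    """Partition nodes into maximal mergeable chains (singletons included)."""
    g = kg.g
    nxt: dict[int, int] = {}
    for u in g.nodes:
        succs = set(g.successors(u))
        if len(succs) != 1:
            continue
        v = succs.pop()
        # u's only successor is v and v's only predecessor is u: every pass
        # through u continues into v, so the merge (consuming all parallel
        # instances between them) is lossless even for repeated nodes.  On
        # linear genomes the start/end occurrences have no entering/leaving
        # edge; a node whose occurrence count exceeds its instance degree
        # must keep its own identity or coordinate coverage would be lost.
        if (v != u and set(g.predecessors(v)) == {u}
                and g.out_degree(u) == len(kg.occ(u))
                and g.in_degree(v) == len(kg.occ(v))):
            nxt[u] = v
    has_prev = set(nxt.values())
    chains: list[list[int]] = []
    visited: set[int] = set()
    for u in nxt:
        if u in has_prev or u in visited:
            continue
        chain = [u]
        visited.add(u)
        while chain[-1] in nxt and nxt[chain[-1]] not in visited:
            v = nxt[chain[-1]]
            chain.append(v)
            visited.add(v)
        chains.append(chain)
    for u in nxt:  # pure cycles: break at an arbitrary node
        if u in visited:
            continue
        chain = [u]
        visited.add(u)
        v = nxt[u]
        while v != u:
            chain.append(v)
            visited.add(v)
            v = nxt[v]
        chains.append(chain)
    for n in g.nodes:
        if n not in visited:
            chains.append([n])
    return chains


def compress_unambiguous_paths(kg: KmerGraph) -> KmerGraph:
    """Merge all uniquely-linked node pairs; idempotent at fixpoint."""
    chains = _chains(kg)
    if all(len(c) == 1 for c in chains):
        return kg
    o = kg.overlap
    out = KmerGraph(kg.k, kg.genome_length, kg.circular, kg.genome_id)
    out.collapse_incomplete = kg.collapse_incomplete
    mapping: dict[int, int] = {}
    internal: set[tuple[int, int]] = set()
    for chain in chains:
        label = kg.label(chain[0]) + "".join(kg.label(n)[o:] for n in chain[1:])
        nid = out.new_node(label, kg.occ(chain[0]))
        for n in chain:
            mapping[n] = nid
        internal.update(zip(chain, chain[1:]))
    for u, v, data in kg.g.edges(data=True):
        if (u, v) in internal:
            continue
        out.g.add_edge(mapping[u], mapping[v], coord=data.get("coord", -1))
    return out


# ---------------------------------------------------------------------------
# 2. unzipping half-decision nodes
# ---------------------------------------------------------------------------


def _occ_junctions(kg: KmerGraph, v: int):
    """Per-occurrence (in-junction, out-junction) k-mer coordinates of v."""
    G = kg.genome_length
    L = len(kg.label(v))
    res = []
    for occ in kg.occ(v):
        cin = occ - 1
        cout = occ + L - (kg.k - 1)
        if kg.circular:
            cin %= G
            cout %= G
        res.append((occ, cin, cout))
    return res


def _unzip_once(kg: KmerGraph) -> KmerGraph | None:
    """Split one half-decision node; return the new graph or None."""
    g = kg.g
    for v in list(g.nodes):
        preds = set(g.predecessors(v))
        succs = set(g.successors(v))
        if v in preds or v in succs:
            continue  # self-loops are genuine tandem-repeat ambiguity
        if g.in_degree(v) != g.out_degree(v):
            continue  # linear-genome end nodes are left alone
        by_succ = len(preds) == 1 and len(succs) >= 2
        by_pred = len(succs) == 1 and len(preds) >= 2
        if not (by_succ or by_pred):
            continue

        in_edges = list(g.in_edges(v, data=True))
        out_edges = list(g.out_edges(v, data=True))
        in_by_coord = {d["coord"]: (u, d) for u, _, d in in_edges}
        out_by_coord = {d["coord"]: (w, d) for _, w, d in out_edges}
        juncs = _occ_junctions(kg, v)
        if len(in_by_coord) != len(in_edges) or len(out_by_coord) != len(out_edges):
            continue  # duplicate junction coordinates: bookkeeping cannot split
        if not all(cin in in_by_coord and cout in out_by_coord for _, cin, cout in juncs):
            continue  # genome start/end occurrence: leave node alone

        # group occurrences by branch
        groups: dict[int, list[tuple[int, int, int]]] = {}
        for occ, cin, cout in juncs:
            branch = out_by_coord[cout][0] if by_succ else in_by_coord[cin][0]
            groups.setdefault(branch, []).append((occ, cin, cout))
        if len(groups) < 2:
            continue

        out_kg = kg.copy()
        label = kg.label(v)
        out_kg.g.remove_node(v)
        for branch, members in groups.items():
            nid = out_kg.new_node(label, [m[0] for m in members])
            for occ, cin, cout in members:
                u = in_by_coord[cin][0]
                w = out_by_coord[cout][0]
                out_kg.g.add_edge(u if u != v else nid, nid, coord=cin)
                out_kg.g.add_edge(nid, w if w != v else nid, coord=cout)
        return out_kg
    return None


def unzip_half_decision_nodes(kg: KmerGraph) -> KmerGraph:
    """Iteratively duplicate half-decision nodes per branch and compress."""
    changed = True
    while changed:
        changed = False
        nxt = _unzip_once(kg)
        if nxt is not None:
            kg = compress_unambiguous_paths(nxt)
            changed = True
    return kg


# ---------------------------------------------------------------------------
# 3. unique-tour collapse
# ---------------------------------------------------------------------------


def _coord_owner(kg: KmerGraph, nodes) -> dict[int, int]:
    return {o: n for n in nodes for o in kg.occ(n)}

def _genome_walk(kg: KmerGraph, start: int, start_occ: int, n_edges: int,
                 owner: dict[int, int]) -> list[int]:
    """Reconstruct the genome's own edge-by-edge walk from coordinates."""
    G = kg.genome_length
    walk = [start]
    occ = start_occ
    node = start
    for _ in range(n_edges):
        nxt_coord = occ + len(kg.label(node)) - kg.overlap
        if kg.circular:
            nxt_coord %= G
        if nxt_coord not in owner:
            raise AssertionError("occurrence bookkeeping broken during collapse")
        node = owner[nxt_coord]
        occ = nxt_coord
        walk.append(node)
    return walk


def _local_spellings(kg: KmerGraph, edges, start: int, cap: int,
                     max_steps: int = 200_000) -> set[str] | None:
    """Spellings of closed walks from ``start`` covering ``edges``.

    Returns None if the enumeration cap or step budget is exceeded.
    """
    succs, mult = _edge_multiset(edges)
    total = sum(mult.values())
    walks = iter_eulerian_walks(succs, mult, start, total, cap, max_steps)
    if walks is None:
        return None
    return {spell_path(kg, w) for w in walks if w[-1] == w[0]}


def _collapse_whole_graph(kg: KmerGraph, cap: int) -> KmerGraph | None:
    """Collapse the entire graph to one node if its tour spelling is unique."""
    g = kg.g
    if g.number_of_edges() == 0 or g.number_of_nodes() == 0:
        return None
    if not kg.circular:
        return None  # linear graphs are fully reduced by compress/unzip
    if not nx.is_weakly_connected(g):
        return None
    if not kg.is_balanced():
        return None
    start = min(g.nodes)
    spellings = _local_spellings(kg, list(g.edges()), start, cap)
    if spellings is None:
        kg.collapse_incomplete = True
        return None
    # canonicalize by rotation: spellings all start/end at `start`, and for a
    # balanced graph distinct linear spellings may still be rotations of one
    # cyclic sequence
    o = kg.overlap

    def cyc(s: str) -> str:
        core = s[: len(s) - len(kg.label(start))]
        d = core + core
        return min(d[i : i + len(core)] for i in range(len(core))) if core else ""

    cyclic = {cyc(s) for s in spellings}
    if len(cyclic) != 1:
        return None
    # rebuild the genome's own tour from coordinates so the collapsed label
    # is anchored at a real occurrence
    owner = _coord_owner(kg, g.nodes)
    anchor = min(owner)
    start_node = owner[anchor]
    walk = _genome_walk(kg, start_node, anchor, g.number_of_edges(), owner)
    if walk[-1] != walk[0]:
        raise AssertionError("genome walk does not close on balanced graph")
    full = spell_path(kg, walk)
    out = KmerGraph(kg.k, kg.genome_length, kg.circular, kg.genome_id)
    out.collapse_incomplete = kg.collapse_incomplete
    core = full[: kg.genome_length]
    out.new_node(core + core[:o], [anchor])
    return out


def _collapse_pendant(kg: KmerGraph, cap: int) -> KmerGraph | None:
    """Collapse one pendant cycle-tree hanging off a boundary node.

    A boundary node ``b`` with exactly one external in- and out-edge
    instance plus internal edges into a region S (a weak component of the
    graph minus b) is collapsed together with S when the local closed-walk
    spelling from b is unique: the single genome pass through b must then
    consume the whole region.
    """
    g = kg.g
    for b in list(g.nodes):
        if g.degree(b) <= 2:
            continue
        rest = g.subgraph([n for n in g.nodes if n != b])
        for S in nx.weakly_connected_components(rest):
            region = S | {b}
            internal_edges = [(u, v, d) for u, v, d in g.edges(data=True)
                              if u in region and v in region]
            if not any(u in S or v in S for u, v, _ in internal_edges):
                continue
            ext_in = [(u, d) for u, v, d in g.in_edges(b, data=True) if u not in region]
            ext_out = [(w, d) for _, w, d in g.out_edges(b, data=True) if w not in region]
            if len(ext_in) != 1 or len(ext_out) != 1:
                continue
            # S nodes must be balanced and fully internal (true by construction)
            if any(g.in_degree(n) != g.out_degree(n) for n in S):
                continue
            spellings = _local_spellings(kg, [(u, v) for u, v, _ in internal_edges], b, cap)
            if spellings is None:
                kg.collapse_incomplete = True
                continue
            if len(spellings) != 1:
                continue
            # anchor at the entry occurrence of b implied by the external in-edge
            entry = ext_in[0][1]["coord"] + 1
            if kg.circular:
                entry %= kg.genome_length
            owner = _coord_owner(kg, region)
            if entry not in owner or owner[entry] != b:
                continue
            walk = _genome_walk(kg, b, entry, len(internal_edges), owner)
            if walk[-1] != b:
                raise AssertionError("pendant walk does not return to boundary")
            label = spell_path(kg, walk)
            out = kg.copy()
            for n in region:
                out.g.remove_node(n)
            nid = out.new_node(label, [entry])
            out.g.add_edge(ext_in[0][0], nid, coord=ext_in[0][1]["coord"])
            out.g.add_edge(nid, ext_out[0][0], coord=ext_out[0][1]["coord"])
            return out
    return None


def collapse_unique_tour_components(kg: KmerGraph, cap: int = 64) -> KmerGraph:
    """Collapse every region with a unique Eulerian tour into a single node."""
    whole = _collapse_whole_graph(kg, cap)
    if whole is not None:
        return whole
    changed = True
    while changed:
        changed = False
        nxt = _collapse_pendant(kg, cap)
        if nxt is not None:
            kg = compress_unambiguous_paths(nxt)
            changed = True
            whole = _collapse_whole_graph(kg, cap)
            if whole is not None:
                return whole
    return kg


# ---------------------------------------------------------------------------
# fixpoint
# ---------------------------------------------------------------------------


def _signature(kg: KmerGraph):
    nodes = tuple(sorted((kg.label(n), tuple(kg.occ(n))) for n in kg.g.nodes))
    edges = tuple(sorted((kg.label(u), kg.label(v), d.get("coord", -1))
                         for u, v, d in kg.g.edges(data=True)))
    return nodes, edges


def simplify(kg: KmerGraph, collapse: bool = True, cap: int = 64) -> KmerGraph:
    """Apply the three lossless transformations to fixpoint.

    ``collapse=False`` disables the unique-tour collapse (debugging aid).
    """
    for _ in range(MAX_FIXPOINT_ROUNDS):
        before = _signature(kg)
        kg = compress_unambiguous_paths(kg)
        kg = unzip_half_decision_nodes(kg)
        if collapse:
            kg = collapse_unique_tour_components(kg, cap=cap)
        if _signature(kg) == before:
            return kg
    raise RuntimeError("simplification did not reach a fixpoint")
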