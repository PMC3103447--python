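"""Finishing complexity, the C-statistic, repeat binning and tuned inserts.

Finishing complexity estimates the number of targeted wet-lab experiments
(e.g. PCR) needed to pair up the in- and out-edges of every repeat node.
Resolving one repeat of degree ``a`` by trying an arbitrary in-edge against
candidate out-edges costs at worst (a-1) + (a-2) + ... + 1 experiments (the
last pairing is implicit), so a node contributes

    C_v = a (a - 1) / 2

and the graph's finishing complexity is the sum over all nodes.

The C-statistic quantifies *localized* complexity: a decision node is
"trivial" if all its successors have distinct label lengths, and
"non-trivial" otherwise (the bubble situation, where spanning mate-pairs
see several equal-length paths and carry no ordering information).  The
C-statistic is the percentage of total finishing complexity held in
non-trivial nodes — complexity that generic long mate-pair libraries
cannot remove.

Tuned library design groups repeat (decision-node) lengths into bins of
width 4k, ranks bins by their share of finishing complexity, and proposes
one insert size per top bin: mean repeat length in the bin plus 3k, so that
pairs just span one repeat of the targeted size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .graph import KmerGraph

__all__ = [
    "node_finishing_complexity",
    "graph_finishing_complexity",
    "classify_triviality",
    "c_statistic",
    "bin_repeat_complexity",
    "tuned_library_sizes",
    "RepeatBin",
    "TunedPlan",
    "ComplexityReport",
    "complexity_report",
]


def node_finishing_complexity(a: int) -> int:
    """Worst-case sequential-pairing experiment count for degree ``a``."""
    if a < 0:
        raise ValueError("degree must be non-negative")
    return a * (a - 1) // 2


def graph_finishing_complexity(kg: KmerGraph) -> int:
    return sum(node_finishing_complexity(kg.degree(n)) for n in kg.g.nodes)


def classify_triviality(kg: KmerGraph, node: int) -> bool:
    """True if the decision node is trivial (all successor lengths distinct).

    Successor lengths are counted per out-edge instance, so parallel edges
    to one successor count as equal lengths (non-trivial): such motifs admit
    multiple equal-length local traversals.
    """
    if not kg.is_decision(node):
        raise ValueError(f"node {node} is not a decision node")
    lengths = [len(kg.label(w)) for _, w in kg.g.out_edges(node)]
    return len(lengths) == len(set(lengths))


def c_statistic(kg: KmerGraph) -> float:
    """Percent of finishing complexity held in non-trivial decision nodes.

    Defined as 0 for graphs with zero total complexity.
    """
    total = 0
    nontrivial = 0
    for n in kg.g.nodes:
        cv = node_finishing_complexity(kg.degree(n))
        total += cv
        if cv and kg.is_decision(n) and not classify_triviality(kg, n):
            nontrivial += cv
    return 100.0 * nontrivial / total if total else 0.0


@dataclass(frozen=True)
class RepeatBin:
    """One 4k-wide repeat-size bin with its complexity share."""

    lo: int
    hi: int
    nodes: tuple[int, ...]
    mean_repeat_length: float
    complexity: int
    complexity_share: float


@dataclass(frozen=True)
class TunedPlan:
    """Insert sizes targeted at the highest-complexity repeat bins."""

    insert_sizes: tuple[int, ...]          # ascending; one per selected bin
    source_bins: tuple[RepeatBin, ...]

    @property
    def empty(self) -> bool:
        return not self.insert_sizes


def bin_repeat_complexity(kg: KmerGraph, k: int | None = None) -> list[RepeatBin]:
    """Group decision nodes by label length into bins of width 4k.

    Bins are anchored at 0 with half-open ranges [4k*i, 4k*(i+1)); empty
    bins are omitted and shares are fractions of total finishing complexity.
    """
    k = kg.k if k is None else k
    width = 4 * k
    total = graph_finishing_complexity(kg)
    members: dict[int, list[int]] = {}
    for n in kg.decision_nodes():
        members.setdefault(len(kg.label(n)) // width, []).append(n)
    bins = []
    for i in sorted(members):
        nodes = tuple(sorted(members[i]))
        lengths = [len(kg.label(n)) for n in nodes]
        cx = sum(node_finishing_complexity(kg.degree(n)) for n in nodes)
        bins.append(RepeatBin(
            lo=width * i,
            hi=width * (i + 1),
            nodes=nodes,
            mean_repeat_length=sum(lengths) / len(lengths),
            complexity=cx,
            complexity_share=cx / total if total else 0.0,
        ))
    return bins


def tuned_library_sizes(kg: KmerGraph, k: int | None = None, n_libraries: int = 2) -> TunedPlan:
    """Derive tuned insert sizes from the repeat-length spectrum.

    The top ``n_libraries`` bins by complexity share each yield one insert:
    round(mean repeat length in bin) + 3k.  Ties between bins go to the
    smaller size range (shorter inserts preferred).  Graphs with fewer
    non-empty bins yield fewer sizes; graphs without decision nodes yield
    an empty plan.
    """
    k = kg.k if k is None else k
    bins = bin_repeat_complexity(kg, k)
    if not bins:
        return TunedPlan((), ())
    ranked = sorted(bins, key=lambda b: (-b.complexity_share, b.lo))
    chosen = ranked[:n_libraries]
    sized = sorted((round(b.mean_repeat_length) + 3 * k, b) for b in chosen)
    return TunedPlan(tuple(s for s, _ in sized), tuple(b for _, b in sized))


@dataclass
class ComplexityReport:
    """Per-node table plus graph-level summaries."""

    table: pd.DataFrame = field(repr=False)
    total_complexity: int = 0
    nontrivial_complexity: int = 0
    c_statistic: float = 0.0
    bins: list[RepeatBin] = field(default_factory=list)
    tuned: TunedPlan = field(default_factory=lambda: TunedPlan((), ()))

    def summary(self) -> dict:
        return {
            "total_finishing_complexity": self.total_complexity,
            "nontrivial_finishing_complexity": self.nontrivial_complexity,
            "c_statistic": self.c_statistic,
            "bins": [
                {"lo": b.lo, "hi": b.hi, "n_nodes": len(b.nodes),
                 "mean_repeat_length": b.mean_repeat_length,
                 "complexity_share": b.complexity_share}
                for b in self.bins
            ],
            "tuned_insert_sizes": list(self.tuned.insert_sizes),
        }


def complexity_report(kg: KmerGraph, k: int | None = None) -> ComplexityReport:
    """Full per-node finishing-complexity report for a simplified graph."""
    k = kg.k if k is None else k
    width = 4 * k
    rows = []
    total = 0
    nontrivial = 0
    for n in sorted(kg.g.nodes):
        a = kg.degree(n)
        cv = node_finishing_complexity(a)
        decision = kg.is_decision(n)
        trivial = classify_triviality(kg, n) if decision else True
        total += cv
        if decision and not trivial:
            nontrivial += cv
        rows.append({
            "node": n,
            "length": len(kg.label(n)),
            "degree": a,
            "complexity": cv,
            "trivial": trivial,
            "bin": (len(kg.label(n)) // width) if decision else -1,
        })
    table = pd.DataFrame(rows, columns=["node", "length", "degree", "complexity", "trivial", "bin"])
    bins = bin_repeat_complexity(kg, k)
    return ComplexityReport(
        table=table,
        total_complexity=total,
        nontrivial_complexity=nontrivial,
        c_statistic=100.0 * nontrivial / total if total else 0.0,
        bins=bins,
        tuned=tuned_library_sizes(kg, k),
    )
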