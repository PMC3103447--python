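"""End-to-end experiment driver: genome -> repeat graph -> metrics ->
simulated mate-pair resolution, plus cohort aggregation.

A single-genome experiment builds and simplifies the order-k repeat graph,
reports finishing complexity and the C-statistic, derives a tuned
mate-pair plan, simulates the requested libraries at Poisson coverage
``lambda`` (10 G / k pairs per library by default), classifies every pair
by the unique-shortest-path heuristic, applies the usable pairs, and
reports the residual finishing complexity.

Cohort runs repeat this over many genomes and k values in ``tuned`` and/or
``standard`` (2000 + 8000 bp) library modes and aggregate the per-genome
statistics, stratified by C-statistic range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genomes import Genome
from .graph import KmerGraph, build_graph
from .simplify import simplify
from .complexity import ComplexityReport, complexity_report
from .matepairs import LibrarySpec, required_pair_count, sample_matepairs
from .resolution import (
    ClassifiedPair,
    ExperimentStats,
    PathOracle,
    ResolutionOutcome,
    MatePairCategory,
    apply_resolutions,
    classify_matepair,
    experiment_stats,
)

logger = logging.getLogger("matetune")

STANDARD_LIBRARIES = (2000, 8000)
C_STAT_STRATUM_WIDTH = 10


@dataclass
class ExperimentReport:
    """Bundle of everything a single-genome experiment produced."""

    genome_id: str
    genome_length: int
    k: int
    mode: str
    library_sizes: tuple[int, ...]
    pairs_per_library: int
    seed: int
    rate: float
    graph: KmerGraph = field(repr=False)
    complexity: ComplexityReport = field(repr=False)
    classified: list[ClassifiedPair] = field(repr=False)
    outcome: ResolutionOutcome | None = field(repr=False)
    stats: ExperimentStats | None

    def header(self) -> dict:
        return {
            "genome": self.genome_id,
            "G": self.genome_length,
            "k": self.k,
            "mode": self.mode,
            "library_sizes": list(self.library_sizes),
            "pairs_per_library": self.pairs_per_library,
            "lambda": self.rate,
            "seed": self.seed,
            "version": __version__,
        }

    def summary(self) -> dict:
        doc = self.header()
        doc.update(self.complexity.summary())
        if self.stats is not None:
            doc["stats"] = self.stats.as_dict()
        return doc


def _resolve_library_sizes(mode: str | Sequence[int], report: ComplexityReport,
                           k: int) -> tuple[str, tuple[int, ...]]:
    if isinstance(mode, str):
        if mode == "tuned":
            return "tuned", tuple(report.tuned.insert_sizes)
        if mode == "standard":
            return "standard", STANDARD_LIBRARIES
        raise ValueError(f"unknown library mode {mode!r}")
    sizes = tuple(int(x) for x in mode)
    if any(s < k for s in sizes):
        raise ValueError("library insert sizes must be >= k")
    return "explicit", sizes


def run_genome_experiment(genome: Genome, k: int,
                          libraries: str | Sequence[int] = "tuned",
                          rate: float = 10.0, seed: int = 0,
                          collapse: bool = True,
                          simplified: KmerGraph | None = None) -> ExperimentReport:
    """Run the full single-genome pipeline.

    ``libraries`` is ``"tuned"``, ``"standard"`` (2000 + 8000 bp) or an
    explicit list of insert sizes.  Each library receives
    ceil(rate * G / k) pairs.  ``simplified`` lets callers reuse an already
    simplified graph for the same (genome, k).
    """
    if len(genome) < k:
        raise ValueError(f"genome {genome.id!r} shorter than k = {k}")
    kg = simplified if simplified is not None else simplify(build_graph(genome, k), collapse=collapse)
    report = complexity_report(kg, k)
    mode, sizes = _resolve_library_sizes(libraries, report, k)
    # inserts that cannot fit the genome are meaningless; drop with a log
    sizes = tuple(s for s in sizes if s <= len(genome))
    n = required_pair_count(len(genome), k, rate)
    logger.info("experiment %s k=%d mode=%s libs=%s n=%d seed=%d",
                genome.id, k, mode, sizes, n, seed)
    if not sizes:
        return ExperimentReport(genome.id, len(genome), k, mode, (), n, seed,
                                rate, kg, report, [], None, None)

    oracle = PathOracle(kg)
    classified: list[ClassifiedPair] = []
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    for size, child in zip(sizes, children):
        rng = np.random.default_rng(child)
        lib = LibrarySpec(mean_insert=max(size, k), read_length=k, n_pairs=n)
        for mp in sample_matepairs(genome, lib, rng):
            classified.append(classify_matepair(kg, genome, mp, oracle))
    usable = [c for c in classified if c.category == MatePairCategory.USABLE]
    outcome = apply_resolutions(kg, usable)
    stats = experiment_stats(classified, outcome)
    return ExperimentReport(genome.id, len(genome), k, mode, sizes, n, seed,
                            rate, kg, report, classified, outcome, stats)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def c_stat_stratum(c: float, width: int = C_STAT_STRATUM_WIDTH) -> str:
    """Width-10 C-statistic stratum label; 100 falls in [90, 100]."""
    lo = min(int(c // width) * width, 100 - width)
    return f"[{lo},{lo + width}]" if lo + width == 100 else f"[{lo},{lo + width})"


def run_cohort(genomes: Iterable[Genome], ks: Sequence[int],
               modes: Sequence[str | Sequence[int]] = ("tuned", "standard"),
               rate: float = 10.0, seed: int = 0) -> pd.DataFrame:
    """Run experiments over a cohort; one row per (genome, k, mode).

    Per-genome failures are logged and skipped; the number of failures is
    recorded in ``df.attrs["failures"]``.  All stochastic stages derive
    from the one root seed, so repeated runs are identical.
    """
    genomes = list(genomes)
    rows = []
    failures = 0
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(genomes) * len(ks) * len(modes))]
    i = 0
    for genome in genomes:
        for k in ks:
            simplified = None
            for mode in modes:
                exp_seed = seeds[i]
                i += 1
                try:
                    rep = run_genome_experiment(genome, k, libraries=mode,
                                                rate=rate, seed=exp_seed,
                                                simplified=simplified)
                    simplified = rep.graph
                except Exception:
                    logger.exception("experiment failed: %s k=%d mode=%s", genome.id, k, mode)
                    failures += 1
                    continue
                row = {
                    "genome": genome.id,
                    "G": len(genome),
                    "k": k,
                    "mode": rep.mode,
                    "library_sizes": ",".join(map(str, rep.library_sizes)),
                    "n_pairs_per_library": rep.pairs_per_library,
                    "seed": exp_seed,
                    "total_complexity": rep.complexity.total_complexity,
                    "c_statistic": rep.complexity.c_statistic,
                    "c_stat_stratum": c_stat_stratum(rep.complexity.c_statistic),
                }
                if rep.stats is not None:
                    row.update(rep.stats.as_dict())
                else:
                    row.update({"PathLenMatch": np.nan, "CrossFork": np.nan,
                                "MatchSeq": np.nan, "Unique": np.nan,
                                "Usable": np.nan, "ComplReduc": 0.0,
                                "n_pairs": 0})
                rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    return df


STAT_COLUMNS = ["PathLenMatch", "CrossFork", "MatchSeq", "Unique", "Usable", "ComplReduc"]


def cohort_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic means of the experiment statistics per (k, mode)."""
    cols = [c for c in STAT_COLUMNS + ["c_statistic"] if c in df.columns]
    return df.groupby(["k", "mode"])[cols].mean().reset_index()
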