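"""Idealized mate-pair simulation and graph placement.

A library of mean insert ``l`` produces pairs whose exact insert ``d`` is
drawn from a Gaussian with mean ``l`` and standard deviation ``0.1 l``
(rounded to whole nucleotides), mimicking real library construction, while
the analysis assumes ``d`` is known exactly for each pair.  A pair starting
at ``s`` consists of two reads of length k covering [s, s+k) and
[s+d-k, s+d); starts are uniform along the genome.

Coverage: with lambda * G / k pairs the number of pair arrivals in any
k-nt window is Poisson(lambda); at the default lambda = 10 a window is
missed with probability e^-10 ~ 4.5e-5, so virtually every node bordering
a repeat receives at least one pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genomes import Genome
from .graph import KmerGraph, Placement

__all__ = [
    "LibrarySpec",
    "MatePair",
    "CoverageModel",
    "required_pair_count",
    "sample_matepairs",
    "place_ends",
]

MAX_REDRAWS = 1000


@dataclass(frozen=True)
class LibrarySpec:
    """A mate-pair library: mean insert l, sd = 0.1 l, read length k."""

    mean_insert: int
    read_length: int
    n_pairs: int

    def __post_init__(self) -> None:
        if self.mean_insert < self.read_length:
            raise ValueError("mean insert must be >= read length")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    @property
    def sd(self) -> float:
        return 0.1 * self.mean_insert


@dataclass(frozen=True)
class MatePair:
    """One simulated pair: start s and exact insert d (both known)."""

    start: int
    insert: int
    read_length: int

    @property
    def read1(self) -> tuple[int, int]:
        return self.start, self.start + self.read_length

    @property
    def read2(self) -> tuple[int, int]:
        return self.start + self.insert - self.read_length, self.start + self.insert


@dataclass(frozen=True)
class CoverageModel:
    """Poisson arrival model for pair starts; lambda is the mean number of
    arrivals per k-nt window."""

    rate: float = 10.0

    def required_pairs(self, genome_length: int, k: int) -> int:
        return required_pair_count(genome_length, k, self.rate)

    def miss_probability(self) -> float:
        """Probability that a k-window receives no pair start."""
        return math.exp(-self.rate)


def required_pair_count(G: int, k: int, rate: float = 10.0) -> int:
    """ceil(rate * G / k) pairs guarantee ~Poisson(rate) arrivals per window."""
    if G < k or k <= 0 or rate <= 0:
        raise ValueError("need G >= k > 0 and rate > 0")
    return math.ceil(rate * G / k)


def sample_matepairs(genome: Genome, lib: LibrarySpec,
                     seed: int | np.random.Generator = 0) -> list[MatePair]:
    """Draw ``lib.n_pairs`` mate-pairs along the genome.

    Inserts are round(Normal(l, 0.1 l)) redrawn while d < k (or, on linear
    genomes, while the pair does not fit); starts are uniform.  Circular
    genomes wrap.  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = len(genome)
    k = lib.read_length
    d = np.rint(rng.normal(lib.mean_insert, lib.sd, size=lib.n_pairs)).astype(int)
    for _ in range(MAX_REDRAWS):
        bad = d < k
        if not genome.circular:
            bad |= d > G
        if not bad.any():
            break
        d[bad] = np.rint(rng.normal(lib.mean_insert, lib.sd, size=int(bad.sum()))).astype(int)
    else:
        raise RuntimeError("could not draw feasible insert sizes")
    if genome.circular:
        s = rng.integers(0, G, size=lib.n_pairs)
    else:
        s = np.array([int(rng.integers(0, G - di + 1)) for di in d])
    return [MatePair(int(si), int(di), k) for si, di in zip(s, d)]


def place_ends(kg: KmerGraph, mp: MatePair) -> tuple[Placement, Placement]:
    """Place both reads on the simplified graph by coordinate look-up.

    Each read is keyed on its start coordinate: it maps to the node
    occurrence whose core contains that coordinate (a read straddling a
    junction sits on the node containing its start).
    """
    p1 = kg.locate(mp.start)
    p2 = kg.locate(mp.start + mp.insert - mp.read_length)
    return p1, p2
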