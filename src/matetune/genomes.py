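"""Synthetic genomes with controlled repeat structure, plus FASTA IO.

The simulation framework operates on complete, finished prokaryotic
chromosomes.  For testing and desk-scale experiments this module generates
random genomes in which the *only* substrings of length >= ``k_guard``
occurring more than once are deliberately planted repeat families.  Two
repeat layouts are supported:

``interspersed``
    ``c`` exact copies of one repeat unit separated by unique background.

``bubble``
    The classic assembly-bubble motif: two repeat units R1 and R2 arranged
    as ``U1 R1 A R2 U2 R1 B R2 U3`` with two unique spacers ``A`` and ``B``
    of equal length.  Mate-pairs spanning both repeats see two equal-length
    paths and carry no ordering information; only pairs tightly spanning a
    single repeat can resolve the motif.

Coordinates are 0-based, half-open, forward strand throughout.  Circular
genomes are stored linearly with implicit wraparound.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("matetune")

DNA_ALPHABET = "ACGT"
_ALPHABET_SET = frozenset(DNA_ALPHABET)

# Bounded number of de-collision sweeps before the generator gives up.
MAX_DECOLLISION_ROUNDS = 100


class GenomePlanError(ValueError):
    """An infeasible or inconsistent genome plan."""


class DecollisionError(RuntimeError):
    """Background could not be made repeat-free within the redraw budget."""


@dataclass(frozen=True)
class PlantedCopy:
    """Record of one planted repeat-unit occurrence (0-based, half-open)."""

    repeat_index: int   # index into GenomePlan.repeats
    unit: int           # 0 for R1, 1 for R2 (bubble); 0 for interspersed
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A single forward-strand DNA sequence.

    Circular chromosomes are stored linearly; k-mer extraction and mate-pair
    placement wrap around the origin.
    """

    id: str
    sequence: str
    circular: bool = True
    planted: list[PlantedCopy] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValueError(f"genome {self.id!r}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def substring(self, start: int, length: int) -> str:
        """Genome substring with wraparound for circular genomes."""
        G = len(self.sequence)
        if length < 0:
            raise ValueError("negative length")
        if self.circular:
            start %= G
            if start + length <= G:
                return self.sequence[start : start + length]
            reps = 1 + (start + length - G) // G
            return (self.sequence + self.sequence * reps)[start : start + length]
        if start < 0 or start + length > G:
            raise IndexError(f"[{start}, {start + length}) outside linear genome of length {G}")
        return self.sequence[start : start + length]


@dataclass(frozen=True)
class RepeatSpec:
    """One planted repeat family.

    ``length`` is the exact repeat-unit length in nt and ``copies`` the
    number of planted occurrences.  ``mode='bubble'`` plants two units (each
    of ``length`` nt, ``copies`` must be 2) in the bubble layout with two
    equal-length unique spacers.  ``motif`` optionally fixes the unit
    sequence (interspersed mode only).

    ``spacer_length`` fixes the unique gaps *between consecutive copies* to
    one common length.  In interspersed mode this produces the chain-bubble
    motif of repeat arrays (e.g. rRNA operons): a repeat node whose
    successors all have equal label lengths, unresolvable except by pairs
    tightly spanning a single copy.  In bubble mode it fixes |A| = |B|
    explicitly instead of the default split.
    """

    length: int
    copies: int = 2
    motif: str | None = None
    mode: str = "interspersed"
    spacer_length: int | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise GenomePlanError("repeat length must be >= 1")
        if self.spacer_length is not None and self.spacer_length < 1:
            raise GenomePlanError("spacer_length must be >= 1")
        if self.copies < 2:
            raise GenomePlanError("repeats need >= 2 copies")
        if self.mode not in ("interspersed", "bubble"):
            raise GenomePlanError(f"unknown repeat mode {self.mode!r}")
        if self.mode == "bubble" and self.copies != 2:
            raise GenomePlanError("bubble mode requires exactly 2 copies of each unit")
        if self.motif is not None:
            if self.mode == "bubble":
                raise GenomePlanError("explicit motifs are not supported in bubble mode")
            if len(self.motif) != self.length:
                raise GenomePlanError("motif length must equal repeat length")
            bad = set(self.motif) - _ALPHABET_SET
            if bad:
                raise GenomePlanError(f"motif has illegal characters {sorted(bad)}")

    @property
    def planted_material(self) -> int:
        """Total nt of repeat material this spec plants."""
        if self.mode == "bubble":
            return 4 * self.length  # two copies each of R1 and R2
        return self.copies * self.length

    @property
    def n_gaps(self) -> int:
        """Unique segments interleaved with this spec's planted copies."""
        if self.mode == "bubble":
            return 3  # spacers A and B plus the segment between inner R2/R1
        return self.copies - 1

    @property
    def fixed_gap_material(self) -> int:
        """nt of unique gaps whose size is pinned by spacer_length."""
        if self.spacer_length is None:
            return 0
        if self.mode == "bubble":
            return 2 * self.spacer_length  # A and B
        return (self.copies - 1) * self.spacer_length

    @property
    def n_fixed_gaps(self) -> int:
        if self.spacer_length is None:
            return 0
        return 2 if self.mode == "bubble" else self.copies - 1


@dataclass(frozen=True)
class GenomePlan:
    """Blueprint for one synthetic genome."""

    total_length: int
    repeats: tuple[RepeatSpec, ...] = ()
    gc_fraction: float = 0.5
    circular: bool = True
    seed: int = 0
    k_guard: int = 35
    id: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "repeats", tuple(self.repeats))
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise GenomePlanError("gc_fraction must lie in [0, 1]")
        if self.k_guard < 2:
            raise GenomePlanError("k_guard must be >= 2")
        planted = sum(r.planted_material for r in self.repeats)
        fixed = sum(r.fixed_gap_material for r in self.repeats)
        free = self._n_gaps() - sum(r.n_fixed_gaps for r in self.repeats)
        if self.total_length < planted + fixed + free * self.k_guard:
            raise GenomePlanError(
                f"total_length {self.total_length} cannot fit {planted} nt of repeat "
                f"material, {fixed} nt of fixed spacers and {free} unique gaps of "
                f">= {self.k_guard} nt"
            )

    def _n_gaps(self) -> int:
        # one gap between consecutive planted elements, plus flanks
        # (one wraparound gap if circular, two ends if linear)
        internal = sum(r.n_gaps for r in self.repeats)
        between = max(len(self.repeats) - 1, 0)
        flanks = 1 if self.circular else 2
        return internal + between + flanks

    # -- config-file round trip -------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "total_length": self.total_length,
            "gc_fraction": self.gc_fraction,
            "circular": self.circular,
            "seed": self.seed,
            "k_guard": self.k_guard,
            "id": self.id,
            "repeats": [
                {"length": r.length, "copies": r.copies, "motif": r.motif,
                 "mode": r.mode, "spacer_length": r.spacer_length}
                for r in self.repeats
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GenomePlan":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        repeats = tuple(RepeatSpec(**r) for r in doc.pop("repeats", []))
        return cls(repeats=repeats, **doc)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(DNA_ALPHABET), size=n, p=probs)) if n else ""


def _gap_sizes(budget: int, n: int, k_guard: int) -> list[int]:
    """Split ``budget`` into n gaps of >= k_guard nt with distinct lengths
    where the budget allows (distinct flank lengths keep isolated repeats
    trivial in the C-statistic sense)."""
    if n == 0:
        if budget:
            raise GenomePlanError("background budget with no gaps")
        return []
    if budget < n * k_guard:
        raise GenomePlanError("background budget leaves gaps shorter than k_guard")
    tri = n * (n - 1) // 2
    delta = min(max(k_guard, 64), (budget - n * k_guard) // tri) if tri else 0
    rest = budget - n * k_guard - delta * tri
    q, r = divmod(rest, n)
    sizes = [k_guard + i * delta + q for i in range(n)]
    sizes[-1] += r
    return sizes


def _layout(plan: GenomePlan, rng: np.random.Generator):
    """Return (elements, gap_sizes) where elements are (spec_idx, unit, seq)
    or None markers and gaps interleave them.

    The returned structure is a list of segments, each a tuple
    (kind, spec_idx, unit, length) with kind in {"gap", "repeat"}; repeat
    segment sequences are filled in by the caller.
    """
    segments: list[list] = []  # [kind, spec_idx, unit, length]

    budget = (plan.total_length
              - sum(r.planted_material for r in plan.repeats)
              - sum(r.fixed_gap_material for r in plan.repeats))
    n_free = plan._n_gaps() - sum(r.n_fixed_gaps for r in plan.repeats)
    sizes = iter(_gap_sizes(budget, n_free, plan.k_guard))

    chains: list[list[list]] = []
    for idx, spec in enumerate(plan.repeats):
        chain: list[list] = []
        fixed = spec.spacer_length
        if spec.mode == "interspersed":
            for c in range(spec.copies):
                if c:
                    chain.append(["gap", idx, None, fixed if fixed else next(sizes)])
                chain.append(["repeat", idx, 0, spec.length])
        else:
            # bubble: R1 A R2 U2 R1 B R2.  |A| = |B| and the balance of U2
            # against the outside unique material (which makes *both* repeat
            # nodes non-trivial) is enforced globally below.
            chain = [
                ["repeat", idx, 0, spec.length],
                ["gap-A", idx, None, fixed if fixed else next(sizes)],
                ["repeat", idx, 1, spec.length],
                ["gap-U2", idx, None, next(sizes)],
                ["repeat", idx, 0, spec.length],
                ["gap-B", idx, None, fixed if fixed else next(sizes)],
                ["repeat", idx, 1, spec.length],
            ]
        chains.append(chain)

    for i, chain in enumerate(chains):
        if i:
            segments.append(["gap", None, None, next(sizes)])
        segments.extend(chain)
    if plan.circular:
        segments.append(["gap", None, None, next(sizes)])
    else:
        segments.insert(0, ["gap", None, None, next(sizes)])
        segments.append(["gap", None, None, next(sizes)])

    # Balance bubble segments for a single-bubble plan: enforce |A| = |B|
    # and make the unique material on the far side of the inner R2 equal in
    # length to the segment U2 between the inner R2 and R1, so that *both*
    # repeat nodes are non-trivial (the full bubble motif).  For circular
    # genomes the far side is the single wraparound gap U3.U1; for linear
    # genomes it is the trailing gap U3 (the leading gap U1 absorbs slack).
    if len(plan.repeats) == 1 and plan.repeats[0].mode == "bubble":
        kg = plan.k_guard
        fixed_s = plan.repeats[0].spacer_length
        a = next(s for s in segments if s[0] == "gap-A")
        b = next(s for s in segments if s[0] == "gap-B")
        u2 = next(s for s in segments if s[0] == "gap-U2")
        outside = [s for s in segments if s[0] == "gap"]
        total = a[3] + b[3] + u2[3] + sum(s[3] for s in outside)
        if plan.circular:
            # 2*s_len + 2*t = total with t = |U2| = |U3.U1|
            if total % 2:
                raise GenomePlanError(
                    "circular bubble plan needs an even background budget; "
                    "adjust total_length by 1 nt")
            half = total // 2
            if fixed_s is not None:
                s_len, t = fixed_s, half - fixed_s
            else:
                s_len = max(kg, half // 3)
                t = half - s_len
                if t < kg:
                    t, s_len = kg, half - kg
            if s_len < kg or t < kg:
                raise GenomePlanError("bubble plan too tight to balance unique segments")
            a[3] = b[3] = s_len
            u2[3] = outside[0][3] = t
        else:
            lead, trail = outside[0], outside[-1]
            s_len = fixed_s if fixed_s is not None else max(kg, total // 6)
            t = max(kg, total // 4)
            u1 = total - 2 * s_len - 2 * t
            if u1 < kg:
                t = max(kg, (total - 2 * s_len - kg) // 2)
                u1 = total - 2 * s_len - 2 * t
            if u1 < kg or t < kg or s_len < kg:
                raise GenomePlanError("bubble plan too tight to balance unique segments")
            a[3] = b[3] = s_len
            u2[3] = trail[3] = t
            lead[3] = u1

    assert sum(s[3] for s in segments) == plan.total_length
    return segments


def _planted_intervals(planted: Sequence[PlantedCopy]) -> list[tuple[int, int]]:
    return [(p.start, p.end) for p in planted]


def _in_any_interval(pos: int, k: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos and pos + k <= e for s, e in intervals)


def _duplicate_kmer_positions(seq: str, k: int, circular: bool) -> dict[str, list[int]]:
    G = len(seq)
    doubled = seq + seq[: k - 1] if circular else seq
    n = G if circular else G - k + 1
    seen: dict[str, list[int]] = {}
    for i in range(n):
        km = doubled[i : i + k]
        seen.setdefault(km, []).append(i)
    return {km: pos for km, pos in seen.items() if len(pos) > 1}


def generate_genome(plan: GenomePlan) -> Genome:
    """Generate a genome realizing ``plan``.

    The planted repeat copies are the only substrings of length >=
    ``plan.k_guard`` occurring more than once; background positions creating
    accidental duplicates are redrawn (bounded number of sweeps).
    Deterministic for a fixed ``plan.seed``.
    """
    rng = np.random.default_rng(plan.seed)
    segments = _layout(plan, rng)

    # draw repeat-unit sequences
    units: dict[tuple[int, int], str] = {}
    for idx, spec in enumerate(plan.repeats):
        units[(idx, 0)] = spec.motif or _random_dna(rng, spec.length, plan.gc_fraction)
        if spec.mode == "bubble":
            units[(idx, 1)] = _random_dna(rng, spec.length, plan.gc_fraction)

    chars: list[str] = []
    planted: list[PlantedCopy] = []
    pos = 0
    background_pos: list[tuple[int, int]] = []  # (start, length) of each gap
    for kind, idx, unit, length in segments:
        if kind == "repeat":
            seq = units[(idx, unit)]
            planted.append(PlantedCopy(idx, unit, pos, pos + length))
            chars.append(seq)
        else:
            background_pos.append((pos, length))
            chars.append(_random_dna(rng, length, plan.gc_fraction))
        pos += length
    seq = "".join(chars)
    assert len(seq) == plan.total_length

    intervals = _planted_intervals(planted)
    k = plan.k_guard
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1").copy()
    alphabet = np.array(list(DNA_ALPHABET))
    probs = np.array([(1 - plan.gc_fraction) / 2, plan.gc_fraction / 2,
                      plan.gc_fraction / 2, (1 - plan.gc_fraction) / 2])
    bg_mask = np.zeros(plan.total_length, dtype=bool)
    for s, L in background_pos:
        bg_mask[s : s + L] = True

    for _round in range(MAX_DECOLLISION_ROUNDS):
        seq = "".join(arr)
        dups = _duplicate_kmer_positions(seq, k, plan.circular)
        offenders: set[int] = set()
        for km, positions in dups.items():
            unplanned = [p for p in positions if not _in_any_interval(p, k, intervals)]
            if unplanned:
                # redraw one background base inside one unplanned occurrence
                offenders.add(unplanned[-1])
        if not offenders:
            genome = Genome(plan.id, seq, plan.circular, planted)
            _verify_planted(genome, plan)
            return genome
        for p in sorted(offenders):
            window = [(p + j) % plan.total_length for j in range(k)]
            bg = [j for j in window if bg_mask[j]]
            if not bg:  # duplicate entirely inside planted material but not
                # aligned to a planted copy; redraw is impossible
                raise DecollisionError(
                    f"unplanned duplicate {k}-mer at {p} overlaps no background"
                )
            j = int(rng.choice(bg))
            arr[j] = rng.choice(alphabet, p=probs)
    raise DecollisionError(
        f"could not de-collide background within {MAX_DECOLLISION_ROUNDS} sweeps"
    )


def _verify_planted(genome: Genome, plan: GenomePlan) -> None:
    units: dict[tuple[int, int], str] = {}
    for copy in genome.planted:
        s = genome.sequence[copy.start : copy.end]
        key = (copy.repeat_index, copy.unit)
        if key in units and units[key] != s:
            raise DecollisionError("planted copies diverged during de-collision")
        units[key] = s


def synthetic_cohort(n_genomes: int = 20, seed: int = 0,
                     total_length: int = 50_000, k_guard: int = 35) -> list[Genome]:
    """Desk-scale stand-in for a panel of complete bacterial genomes.

    Each genome is circular, 50 kb by default, and carries the repeat
    features that drive finishing complexity in prokaryotes: two 4-copy
    repeat arrays with equal-length spacers (chain bubbles, e.g. rRNA
    operon-like), one 3-copy repeat with distinct-length flanks (trivial
    complexity), and one two-unit assembly bubble with equal-length
    spacers.  Family lengths vary per genome; everything derives from one
    root seed.
    """
    rng = np.random.default_rng(seed)
    genomes: list[Genome] = []
    failures = 0
    while len(genomes) < n_genomes:
        s = int(rng.integers(0, 2**31))
        r = np.random.default_rng(s)
        repeats = [
            RepeatSpec(length=int(r.integers(150, 220)), copies=4, spacer_length=300),
            RepeatSpec(length=int(r.integers(220, 280)), copies=4, spacer_length=300),
            RepeatSpec(length=int(r.integers(400, 520)), copies=3),
            RepeatSpec(length=int(r.integers(120, 180)), copies=2, mode="bubble",
                       spacer_length=300),
        ]
        plan = GenomePlan(total_length=total_length, repeats=repeats, seed=s,
                          k_guard=k_guard, circular=True,
                          id=f"synth{len(genomes):02d}")
        try:
            genomes.append(generate_genome(plan))
        except DecollisionError:
            failures += 1
            if failures > 5 * n_genomes:
                raise
    return genomes


# ---------------------------------------------------------------------------
# FASTA IO
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, circular: bool = True, strict: bool = True) -> list[Genome]:
    """Read genomes from FASTA, one Genome per record.

    Sequences are uppercased.  Non-ACGT characters raise in strict mode and
    are replaced by 'A' (with a logged warning) otherwise.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not a FASTA file")
    genomes = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALPHABET_SET
        if bad:
            if strict:
                raise ValueError(f"{path}:{rec.id}: illegal characters {sorted(bad)}")
            logger.warning("%s:%s: masking %d non-ACGT characters", path, rec.id,
                           sum(seq.count(c) for c in bad))
            table = str.maketrans({c: "A" for c in bad})
            seq = seq.translate(table)
        genomes.append(Genome(rec.id, seq, circular=circular))
    return genomes


def write_fasta(genomes: Genome | Iterable[Genome], path: str | Path) -> None:
    """Write one or more genomes as FASTA wrapped at 70 columns."""
    if isinstance(genomes, Genome):
        genomes = [genomes]
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)
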