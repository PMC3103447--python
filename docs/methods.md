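# Methods

## Idealized repeat graphs

A genome is a single forward-strand sequence over {A,C,G,T} with a
circular/linear flag; coordinates are 0-based and half-open throughout.
The order-`k` de Bruijn graph has one node per distinct (k−1)-mer present
in the genome and one directed edge *instance* per k-mer occurrence
(parallel edges for repeated k-mers), so the genome is an Eulerian
traversal of its own graph. Circular genomes wrap around the origin and
contribute exactly G edge instances; every node of a circular graph is
balanced. We treat k-mer size and read length as one parameter `k`: the
graph of an error-free, gap-free sequencing experiment with reads of
length k. Reverse-complement (bi-directed) structure, base-call errors
and coverage gaps are deliberately out of scope; the results are an
upper bound on what mate-pairs can contribute on real data.

Adjacent node labels share exactly k−2 letters (two consecutive
(k−1)-mers overlap by k−2), and this overlap is preserved by every
simplification, so spelled path length is `Σ len(v_j) − (m−1)(k−2)` and
the shortest-path separation defined below coincides with genomic
distance. Every node carries its sorted genome start coordinates and
every edge instance the coordinate of its junction k-mer; this annotation
is maintained exactly through all transformations and is what the
simulator uses for read placement.

## Lossless simplification

Three transformations are iterated to a fixpoint (at most 100 rounds;
order compress → unzip → collapse, immaterial at the fixpoint):

1. **Path compression.** If v is u's only successor and u is v's only
   predecessor (as distinct nodes), every pass through u continues into
   v, so the pair merges into one node (labels concatenated minus the
   overlap, occurrences inherited from u, all parallel instances between
   them consumed). This condition is deliberately neighbor-based, not
   instance-based: a repeated chain of (k−1)-mers with edge multiplicity
   c compresses into a single repeat node whose label length equals the
   repeat length and whose occurrence list has c entries.

2. **Unzipping.** A half-decision node (one distinct predecessor but
   several distinct successors, or the mirror; self-loop-free and
   balanced) is duplicated per branch. Which occurrence follows which
   branch is decided by coordinates (junction k-mer of occurrence o sits
   at o−1 on the in side and o+len−(k−1) on the out side), so the split
   is exact, and all in-edges being parallel instances from one neighbor
   makes it lossless. Resulting unambiguous paths are compressed.

3. **Unique-tour collapse.** A region whose cycle decomposition is a
   tree has a unique Eulerian tour and collapses to one node spelling
   that tour. Detection is *semantic*: candidate regions (the whole
   graph, or a pendant component attached to a boundary node with
   exactly one external in- and out-edge instance) are tested by bounded
   brute-force enumeration of closed-walk spellings (cap 64 complete
   walks, 200k exploration steps). Regions exceeding the budget are left
   uncollapsed — lossless, merely less compact — and flagged on the
   graph. Circuit spellings are compared as cyclic sequences (minimal
   rotation): a figure-eight's two edge orders are rotations of one
   cyclic sequence, so an isolated 2-copy repeat in a circular genome has
   a unique tour and correctly vanishes. The collapsed node's label is
   rebuilt by following genome coordinates, keeping the annotation
   consistent.

A consequence worth stating: under the Eulerian constraint a *lone*
2-copy repeat carries no finishing complexity (its graph has one tour).
Genuine ambiguity requires ≥ 3 copies or interleaved repeat pairs
(bubbles). Tests that need an unresolved isolated repeat therefore
disable the collapse (`simplify(..., collapse=False)`, exposed as
`--no-collapse`).

Losslessness is verified against a brute-force oracle
(`enumerate_eulerian`): iterative backtracking over edge multiplicities
that returns the exact set of traversal spellings (circuits
canonicalized by rotation; linear graphs spelled from the unique
unbalanced start), with an explicit cap so the oracle refuses rather
than silently truncates.

## Finishing complexity and the C-statistic

Resolving a degree-a repeat by targeted experiments — pick an in-edge,
test candidate out-edges until the mate is found, repeat — costs at
worst (a−1)+(a−2)+…+1 tests, the last pairing being implicit, giving
`C_v = a(a−1)/2` and graph complexity `Σ C_v`. The degree a is the
edge-instance in/out degree (equal on balanced graphs; max(in, out)
covers linear-fixture end nodes). A worst-case reading is used
throughout; an expected-case variant would rescale all complexity
numbers but not the tuned-vs-standard contrast.

A decision node is *trivial* when all its successors have distinct label
lengths, counted per out-edge instance so parallel edges to one
successor register as equal lengths (non-trivial). The C-statistic is
100 × (complexity in non-trivial nodes) / (total complexity), defined as
0 for zero-complexity graphs.

## Tuned library sizes

Decision-node label lengths are binned at width 4k, anchored at 0,
half-open. Each bin's complexity share is its summed C_v over the graph
total; the bin's repeat size is the unweighted mean label length of its
members. The two highest-share bins (ties: smaller sizes first, shorter
inserts being the more useful end) each yield one insert,
`round(mean) + 3k`, so a pair spans one repeat of the targeted size plus
a read length of unique anchor on each side. Graphs with one non-empty
bin yield one size; graphs without decision nodes yield an empty plan.

## Mate-pair simulation and resolution

A library (mean insert l, sd fixed at 0.1 l, read length k) draws each
pair's exact insert d = round(Normal(l, 0.1 l)), redrawn while d < k or,
on linear genomes, while the pair does not fit (bounded retries); the
start s is uniform; reads cover [s, s+k) and [s+d−k, s+d), wrapping on
circular genomes. Each library gets n = ⌈λG/k⌉ pairs with λ = 10 —
arrivals per k-window are then Poisson(10), missing a window with
probability e^(−10) ≈ 4.5×10⁻⁵ — and multi-library experiments use n per
library. d is treated as exactly known downstream (the idealization that
isolates insert-size effects from size-uncertainty effects).

Reads are placed by coordinate lookup: a read belongs to the node
occurrence whose core contains its start (cores partition the genome;
a read straddling a junction overhangs its node by at most one letter).
Classification per pair: SAME_NODE (no information), ADJACENT (joined by
an edge; spans no repeat), else compute the minimal separation
D* = min over node paths of Σ(len(v_j)−(k−2)) + offset₂ − offset₁ by
Dijkstra with per-source caching; AMBIGUOUS if the shortest-path DAG
carries more than one minimal node-sequence (count capped at 16 —
uniqueness only needs 1 vs >1; parallel instances spell identically and
are not distinct paths), NO_EXACT_MATCH if D* ≠ d − k or the target is
unreachable, otherwise USABLE. For usable pairs the unique path's
spelling is compared against the true genomic substring (seq_match); the
final letter is excused when the second read overhangs the path's last
node.

Usable pairs record an (in-neighbor, out-neighbor) pairing at every
decision node interior to their path. Pairings are accepted per node in
decreasing support order against slot capacities (edge-instance counts
per neighbor); same-support pairings competing for an exhausted slot are
all dropped. A node with r accepted pairings keeps residual complexity
C(max(a−r, 0)) — one accepted pairing fully resolves a degree-2 node,
the last pairing again being implicit. Residual complexity is computed
by this per-node degree reduction, not by re-simplifying the graph.

Experiment statistics follow the usual vocabulary: PathLenMatch%
(D* = d−k, all pairs), CrossFork% (distinct non-adjacent placements, all
pairs), Unique% (unique minimal path, over cross-fork pairs), MatchSeq%
(unique path spelling the true substring, over cross-fork pairs),
Usable% (all pairs), ComplReduc% (relative complexity reduction; 0 with
a flag when the graph had none).

## Synthetic genomes

The generator emulates complete bacterial chromosomes: circular by
default, random background at a chosen GC fraction, with planted exact
repeat families — interspersed copies, arrays with a fixed equal spacer
length (the chain-bubble motif of rRNA-operon-like arrays, whose
interior copy-to-copy pairings are reachable only by pairs tightly
spanning one copy), and the two-unit bubble U1·R1·A·R2·U2·R1·B·R2·U3
with |A| = |B|. Single-bubble plans additionally balance the far-side
unique segments (|U2| = |U3·U1| circular) so both repeat nodes are
non-trivial. Unique gaps otherwise get deliberately distinct lengths
(an ascending ladder ≥ k_guard) so isolated repeats have distinct-length
flanks. After assembly the background is re-drawn at colliding positions
(≤ 100 sweeps) until the planted copies are the only substrings of
length ≥ k_guard occurring twice; with ≥ 5 copies of one unit the
single boundary flank characters collide by pigeonhole over the 4-letter
alphabet, so plans are limited to ≤ 4 copies per family and the
generator raises otherwise.

What the fixtures do *not* model: sequencing errors, reverse strand,
chimeric or mis-sized pairs, plasmids, and the long mosaic repeats of
real genomes. Passing tests therefore demonstrate the graph-theoretic
behavior of the method under its own idealization, not performance on
real sequencing data.

## Scaled-down cohort and problem sizes

The cohort experiment uses 20 synthetic 50 kb genomes (two 4-copy
arrays with 300 nt spacers, one 3-copy distinct-flank repeat, one
bubble), k ∈ {35, 100}, λ = 10 (≈ 14.3k pairs per library at k = 35),
tuned vs 2000+8000 bp modes — sizes chosen so the full comparison runs
in minutes on one CPU while preserving the mechanism that separates the
two designs: interior pairings of equal-spacer arrays are geometrically
inaccessible to 2000+8000 bp pairs. Insert sizes exceeding the genome
length are dropped from a run (an 8000 bp library is meaningless on a
6 kb fixture).

## Numerical and degenerate-case choices

- Insert rounding to whole nucleotides; tuned sizes rounded half-even by
  Python's `round` (tests allow 1 nt).
- Same-node placements with offset₂ ≥ offset₁ use the within-node
  separation directly; wrapped same-node pairs use the minimal closed
  walk.
- Zero-complexity graphs: C-statistic 0, ComplReduc 0 with a flag.
- Shortest-path count cap 16, unique-tour enumeration cap 64 with a
  200k-step exploration budget; both err toward "don't decide" (pair
  ambiguous, region uncollapsed).
- Bin tie-break: higher complexity share first, then smaller repeat-size
  range.
- Per-genome cohort failures are logged and skipped, counted in
  `df.attrs["failures"]`.
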