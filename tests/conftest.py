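import numpy as np
import pytest

from matetune import Genome, GenomePlan, RepeatSpec, build_graph, generate_genome, simplify


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_plan(seed: int, total: int = 1200, k_guard: int = 21) -> GenomePlan:
    """A small random genome plan mixing repeat motifs (seeded)."""
    rng = np.random.default_rng(seed)
    kind = seed % 4
    if kind == 0:
        repeats = []
    elif kind == 1:
        repeats = [RepeatSpec(length=int(rng.integers(30, 70)),
                              copies=int(rng.integers(2, 5)))]
    elif kind == 2:
        repeats = [RepeatSpec(length=int(rng.integers(30, 60)), copies=2, mode="bubble")]
    else:
        repeats = [RepeatSpec(length=int(rng.integers(25, 50)),
                              copies=int(rng.integers(3, 5)),
                              spacer_length=int(rng.integers(40, 80))),
                   RepeatSpec(length=int(rng.integers(30, 60)), copies=2)]
    total_adj = total + (total % 2)  # circular bubble balancing needs even background
    return GenomePlan(total_length=total_adj, repeats=repeats, seed=seed,
                      k_guard=k_guard, circular=bool(seed % 2), id=f"rand{seed}")


@pytest.fixture(scope="session")
def single_repeat_genome() -> Genome:
    """Circular genome with one 2-copy interspersed repeat."""
    plan = GenomePlan(total_length=3000, k_guard=50, seed=2, circular=True,
                      repeats=[RepeatSpec(length=300, copies=2)], id="rep2")
    return generate_genome(plan)


@pytest.fixture(scope="session")
def three_copy_genome() -> Genome:
    """Circular genome with one 3-copy repeat and distinct-length flanks."""
    plan = GenomePlan(total_length=4000, k_guard=50, seed=3, circular=True,
                      repeats=[RepeatSpec(length=300, copies=3)], id="rep3")
    return generate_genome(plan)


@pytest.fixture(scope="session")
def bubble_genome() -> Genome:
    """Circular genome carrying the full bubble motif (|A| = |B|, balanced
    far-side segments) with 150 nt repeat units and 300 nt spacers."""
    plan = GenomePlan(total_length=6000, k_guard=35, seed=11, circular=True,
                      repeats=[RepeatSpec(length=150, copies=2, mode="bubble",
                                          spacer_length=300)], id="bubble")
    return generate_genome(plan)


@pytest.fixture(scope="session")
def array_genome() -> Genome:
    """Circular genome with a 4-copy repeat array and equal 300 nt spacers
    (the chain-bubble motif)."""
    plan = GenomePlan(total_length=20000, k_guard=35, seed=9, circular=True,
                      repeats=[RepeatSpec(length=200, copies=4, spacer_length=300)],
                      id="array")
    return generate_genome(plan)


@pytest.fixture(scope="session")
def bubble_graph(bubble_genome):
    return simplify(build_graph(bubble_genome, 35))


@pytest.fixture(scope="session")
def array_graph(array_genome):
    return simplify(build_graph(array_genome, 35))
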