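import numpy as np
import pytest

from sibjoin import SimulationConfig, simulate
from sibjoin.partition import make_partition
from sibjoin.population import Individual, Population, genotype, make_population


@pytest.fixture
def default_bundle():
    """One simulated population at the reference study conditions."""
    return simulate(SimulationConfig(k=6, m=6, n=40, f=5, seed=11))


@pytest.fixture
def sextet_population():
    """Single-locus sextet whose smallest incompatible subgroup is itself."""
    genos = [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]
    return make_population([(f"i{t}", [g]) for t, g in enumerate(genos)])


@pytest.fixture
def sextet_partition(sextet_population):
    """The sextet as one paternal family with singleton maternal families."""
    ids = [ind.id for ind in sextet_population.individuals]
    return make_partition([[i] for i in ids], [ids])


def random_removal_instance(rng, n_max=9, m_max=2, k_max=4):
    """A random small population with random maternal/paternal partitions."""
    n = int(rng.integers(4, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    k = int(rng.integers(2, k_max + 1))
    inds = tuple(
        Individual(
            f"i{j}",
            tuple(
                genotype(int(rng.integers(k)), int(rng.integers(k)))
                for _ in range(m)
            ),
        )
        for j in range(n)
    )
    pop = Population(inds, tuple(f"L{l}" for l in range(m)))

    def rand_part():
        nb = int(rng.integers(1, n + 1))
        labels = rng.integers(0, nb, size=n)
        blocks = {}
        for j, lab in enumerate(labels):
            blocks.setdefault(int(lab), []).append(f"i{j}")
        return list(blocks.values())

    return pop, make_partition(rand_part(), rand_part())
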