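"""Synthetic polygamous populations with known half-sib structure.

The generator draws an equal number of mothers and fathers (n/f of each),
every parent receiving two independent uniform alleles from {0..k-1} at
each locus.  Children are generated from mother-father pairs: each mother
produces one brood of f full siblings with a father drawn uniformly at
random (with replacement), so a maternal family is a full-sib block of size
f and half-sibling structure arises whenever two mothers draw the same
father — the polygamous regime the clustering heuristic targets.  Children
inherit one uniformly chosen allele from each parent per locus.

Defaults are the reference study conditions: 6 alleles, 6 loci, half-sib
family size 5, population size 40.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .partition import SibPartition, make_partition
from .population import Genotype, Individual, Population, genotype


@dataclass(frozen=True)
class SimulationConfig:
    k: int = 6  # alleles per locus
    m: int = 6  # loci
    n: int = 40  # population size
    f: int = 5  # maternal half-sib family size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2 or self.m < 1 or self.f < 1 or self.n < 1:
            raise ValueError("require k >= 2, m >= 1, f >= 1, n >= 1")


@dataclass(frozen=True)
class TruthBundle:
    """A simulated population with its ground-truth partitions and parents."""

    pop: Population
    truth: SibPartition
    mother_genotypes: tuple[tuple[Genotype, ...], ...]
    father_genotypes: tuple[tuple[Genotype, ...], ...]
    config: SimulationConfig


def _parent_genotypes(rng: np.random.Generator, count: int, m: int, k: int):
    draws = rng.integers(0, k, size=(count, m, 2))
    return tuple(
        tuple(genotype(int(a), int(b)) for a, b in parent) for parent in draws
    )


def simulate(config: SimulationConfig) -> TruthBundle:
    """Generate a population and its true maternal/paternal partitions."""
    rng = np.random.default_rng(config.seed)
    n_fam = config.n // config.f
    if n_fam == 0:
        raise ValueError("family size exceeds population size")
    n = n_fam * config.f
    if n != config.n:
        warnings.warn(
            f"population size {config.n} rounded down to {n} "
            f"(multiple of family size {config.f})",
            stacklevel=2,
        )
    mothers = _parent_genotypes(rng, n_fam, config.m, config.k)
    fathers = _parent_genotypes(rng, n_fam, config.m, config.k)
    # one mate per mother, drawn with replacement: fathers are polygamous
    mates = rng.integers(0, n_fam, size=n_fam)

    width = len(str(n - 1))
    individuals = []
    maternal: list[list[str]] = [[] for _ in range(n_fam)]
    paternal: list[list[str]] = [[] for _ in range(n_fam)]
    for child in range(n):
        mi = child // config.f
        fi = int(mates[mi])
        picks = rng.integers(0, 2, size=(config.m, 2))
        gs = tuple(
            genotype(mothers[mi][l][picks[l, 0]], fathers[fi][l][picks[l, 1]])
            for l in range(config.m)
        )
        iid = f"ind{child:0{width}d}"
        individuals.append(Individual(iid, gs))
        maternal[mi].append(iid)
        paternal[fi].append(iid)
    pop = Population(
        tuple(individuals), tuple(f"L{l}" for l in range(config.m))
    )
    truth = make_partition(maternal, (b for b in paternal if b))
    return TruthBundle(pop, truth, mothers, fathers, config)


def inject_dropout(bundle: TruthBundle, rate: float, seed: int) -> TruthBundle:
    """Set each (individual, locus) genotype to missing with probability rate."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return bundle
    rng = np.random.default_rng(seed)
    pop = bundle.pop
    mask = rng.random(size=(pop.n, pop.m)) < rate
    individuals = tuple(
        Individual(
            ind.id,
            tuple(
                None if mask[i, l] else g for l, g in enumerate(ind.genotypes)
            ),
        )
        for i, ind in enumerate(pop.individuals)
    )
    return replace(
        bundle, pop=Population(individuals, pop.locus_names)
    )
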