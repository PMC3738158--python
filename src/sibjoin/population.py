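"""Diploid microsatellite genotype tables.

A microsatellite allele is a non-negative integer repeat count.  A diploid
genotype at one locus is an *unordered* pair of alleles; a locus that failed
to genotype (allelic dropout) is recorded as fully missing, written ``*`` in
files and represented as :data:`MISSING` (``None``) in memory.

The canonical file dialect is a tab-separated table with one header line
(``id`` followed by two columns ``<locus>.1``/``<locus>.2`` per locus) and one
row per individual.  ``read_population`` and ``write_population`` round-trip
this dialect bit-exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

#: Sentinel for a dropped-out (fully missing) locus.
MISSING = None

#: File token for a missing allele.
DROPOUT_SENTINEL = "*"

Genotype = Optional[tuple[int, int]]


def genotype(a: int, b: int) -> tuple[int, int]:
    """Return the canonical (sorted) form of an unordered genotype.

    ``genotype(1, 2) == genotype(2, 1)``; alleles must be non-negative
    integers.
    """
    a, b = int(a), int(b)
    if a < 0 or b < 0:
        raise ValueError(f"alleles must be non-negative, got ({a}, {b})")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Individual:
    """A genotyped individual: an id and one unordered genotype per locus."""

    id: str
    genotypes: tuple[Genotype, ...]

    @property
    def m(self) -> int:
        return len(self.genotypes)

    def n_typed_loci(self) -> int:
        """Number of loci with a successfully genotyped (non-missing) call."""
        return sum(g is not None for g in self.genotypes)


@dataclass(frozen=True)
class Population:
    """A population of individuals genotyped at the same ``m`` loci."""

    individuals: tuple[Individual, ...]
    locus_names: tuple[str, ...]

    def __post_init__(self) -> None:
        m = len(self.locus_names)
        for ind in self.individuals:
            if ind.m != m:
                raise ValueError(
                    f"individual {ind.id!r} has {ind.m} loci, expected {m}"
                )
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def m(self) -> int:
        return len(self.locus_names)

    def allele_sets(self) -> list[tuple[int, ...]]:
        """Per-locus sorted allele sets A_l (union of observed alleles).

        Missing loci contribute nothing; a locus where every individual
        dropped out has an empty allele set.
        """
        sets: list[set[int]] = [set() for _ in range(self.m)]
        for ind in self.individuals:
            for l, g in enumerate(ind.genotypes):
                if g is not None:
                    sets[l].update(g)
        return [tuple(sorted(s)) for s in sets]

    def by_id(self) -> dict[str, Individual]:
        return {ind.id: ind for ind in self.individuals}


def make_population(
    rows: Iterable[tuple[str, Sequence[Genotype]]],
    locus_names: Sequence[str] | None = None,
) -> Population:
    """Build a Population from ``(id, genotypes)`` rows, normalizing genotypes."""
    inds = []
    for iid, gs in rows:
        norm = tuple(None if g is None else genotype(*g) for g in gs)
        inds.append(Individual(str(iid), norm))
    if locus_names is None:
        m = inds[0].m if inds else 0
        locus_names = tuple(f"L{l}" for l in range(m))
    return Population(tuple(inds), tuple(locus_names))


def allele_summary(pop: Population) -> dict[str, tuple[int, ...]]:
    """Map each locus name to its sorted allele set A_l (k_l = len of it)."""
    return dict(zip(pop.locus_names, pop.allele_sets()))


def _parse_allele(token: str, row: int, col: int):
    if token == DROPOUT_SENTINEL:
        return None
    try:
        v = int(token)
    except ValueError:
        raise ValueError(
            f"row {row}, column {col}: invalid allele token {token!r}"
        ) from None
    if v < 0:
        raise ValueError(f"row {row}, column {col}: negative allele {v}")
    return v


def read_population(path: str | Path) -> Population:
    """Read the canonical genotype TSV (see module docstring)."""
    path = Path(path)
    with path.open() as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "id":
        raise ValueError(f"{path}: first header column must be 'id'")
    allele_cols = header[1:]
    if len(allele_cols) % 2 != 0:
        raise ValueError(
            f"{path}: odd number of allele columns ({len(allele_cols)}); "
            "each locus needs two"
        )
    locus_names = []
    for i in range(0, len(allele_cols), 2):
        name1 = allele_cols[i].rsplit(".", 1)
        name2 = allele_cols[i + 1].rsplit(".", 1)
        if len(name1) != 2 or len(name2) != 2 or name1[0] != name2[0]:
            raise ValueError(
                f"{path}: allele columns {allele_cols[i]!r}/{allele_cols[i+1]!r} "
                "do not form a '<locus>.1'/'<locus>.2' pair"
            )
        locus_names.append(name1[0])
    m = len(locus_names)

    rows: list[tuple[str, list[Genotype]]] = []
    for r, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 1 + 2 * m:
            raise ValueError(
                f"{path}: row {r} has {len(fields)} fields, expected {1 + 2 * m}"
            )
        iid = fields[0]
        gs: list[Genotype] = []
        for l in range(m):
            a = _parse_allele(fields[1 + 2 * l], r, 2 + 2 * l)
            b = _parse_allele(fields[2 + 2 * l], r, 3 + 2 * l)
            if (a is None) != (b is None):
                # Only full-locus dropout is modeled; a half-read locus is
                # degraded to missing.
                warnings.warn(
                    f"{path}: row {r}, locus {locus_names[l]!r}: partially "
                    "missing genotype normalized to full dropout",
                    stacklevel=2,
                )
                gs.append(None)
            elif a is None:
                gs.append(None)
            else:
                gs.append(genotype(a, b))
        rows.append((iid, gs))
    return make_population(rows, locus_names)


def write_population(pop: Population, path: str | Path) -> None:
    """Write the canonical genotype TSV; inverse of :func:`read_population`."""
    path = Path(path)
    with path.open("w") as fh:
        cols = ["id"]
        for name in pop.locus_names:
            cols += [f"{name}.1", f"{name}.2"]
        fh.write("\t".join(cols) + "\n")
        for ind in pop.individuals:
            fields = [ind.id]
            for g in ind.genotypes:
                if g is None:
                    fields += [DROPOUT_SENTINEL, DROPOUT_SENTINEL]
                else:
                    fields += [str(g[0]), str(g[1])]
            fh.write("\t".join(fields) + "\n")
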