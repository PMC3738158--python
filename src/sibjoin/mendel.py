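"""Mendelian compatibility predicates and feasible-parent-set algebra.

Half-sibship property: a group is a feasible half-sib family iff at every
locus there is an unordered allele pair {a_i, a_j} — the shared parent's
genotype — such that every member carries at least one copy of a_i or a_j.

Full-sib feasibility combines the 4-allele property (at most four alleles per
locus across the group) with the 2-allele property: the locus alleles can be
split into a maternal and a paternal genotype so that every member gets one
allele from each.

The parent-set algebra is the incremental form of the half-sibship check used
by the clustering heuristic: each individual starts with the set of all
candidate shared-parent genotypes per locus (O(k) of them), and joining
groups intersects these sets; a group is half-sib compatible iff the fold of
its members' parent sets is non-empty at every locus.  Dropout loci are
unrestricted and impose nothing.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Optional, Sequence

from .population import Individual

#: Per-locus marker: no restriction on the shared parent (dropout locus).
UNRESTRICTED = None

LocusParentSet = Optional[frozenset[tuple[int, int]]]


@dataclass(frozen=True)
class ParentSet:
    """Per-locus sets of feasible shared-parent genotypes.

    Each locus entry is either :data:`UNRESTRICTED` (``None``) or a frozenset
    of unordered candidate genotypes.  ``UNRESTRICTED`` is the identity of
    intersection.
    """

    loci: tuple[LocusParentSet, ...]

    @property
    def m(self) -> int:
        return len(self.loci)

    def empty_loci(self) -> list[int]:
        """Indices of loci where no candidate parent genotype remains."""
        return [l for l, s in enumerate(self.loci) if s is not None and not s]

    def is_feasible(self) -> bool:
        return not self.empty_loci()


def _genotypes_covering(alleles: Iterable[int], a: int, b: int) -> frozenset:
    """All unordered genotypes over ``alleles`` containing allele a or b."""
    pool = sorted(set(alleles) | {a, b})
    out = set()
    for x, y in combinations_with_replacement(pool, 2):
        if x == a or x == b or y == a or y == b:
            out.add((x, y))
    return frozenset(out)


def initial_parent_set(
    x: Individual, allele_sets: Sequence[Sequence[int]]
) -> ParentSet:
    """The singleton parent set of one individual.

    At a typed locus (a, b) this is every unordered genotype over A_l with at
    least one copy of a or b (at most 2k-1 genotypes); a dropout locus is
    unrestricted.
    """
    if len(allele_sets) != x.m:
        raise ValueError("allele_sets length must equal the locus count")
    loci: list[LocusParentSet] = []
    for g, A in zip(x.genotypes, allele_sets):
        if g is None:
            loci.append(UNRESTRICTED)
        else:
            loci.append(_genotypes_covering(A, g[0], g[1]))
    return ParentSet(tuple(loci))


def intersect_parent_sets(p: ParentSet, q: ParentSet) -> ParentSet:
    """Per-locus intersection; UNRESTRICTED is the identity element."""
    if p.m != q.m:
        raise ValueError(f"locus count mismatch: {p.m} vs {q.m}")
    loci: list[LocusParentSet] = []
    for s, t in zip(p.loci, q.loci):
        if s is None:
            loci.append(t)
        elif t is None:
            loci.append(s)
        else:
            loci.append(s & t)
    return ParentSet(tuple(loci))


def fold_parent_sets(
    group: Iterable[Individual], allele_sets: Sequence[Sequence[int]]
) -> ParentSet:
    """Intersection of the members' initial parent sets."""
    ps: ParentSet | None = None
    for ind in group:
        one = initial_parent_set(ind, allele_sets)
        ps = one if ps is None else intersect_parent_sets(ps, one)
    if ps is None:
        raise ValueError("empty group")
    return ps


def half_sib_compatible(
    group: Iterable[Individual],
    allele_sets: Sequence[Sequence[int]] | None = None,
) -> bool:
    """True iff some allele pair covers every typed member at every locus.

    Equivalent to the fold of the members' parent sets being non-empty at
    every locus (the shared-parent pair can be taken among observed alleles,
    so ``allele_sets`` is not needed; it is accepted for signature parity).
    """
    members = list(group)
    if not members:
        raise ValueError("empty group")
    m = members[0].m
    for l in range(m):
        gs = [ind.genotypes[l] for ind in members]
        gs = [g for g in gs if g is not None]
        if len(gs) <= 2:
            continue  # two genotypes are always coverable by one allele each
        observed = sorted({a for g in gs for a in g})
        if not any(
            all(g[0] in pair or g[1] in pair for g in gs)
            for pair in combinations_with_replacement(observed, 2)
        ):
            return False
    return True


def full_sib_compatible(
    group: Iterable[Individual],
    allele_sets: Sequence[Sequence[int]] | None = None,
) -> bool:
    """4-allele + 2-allele feasibility of a candidate full-sib family.

    At every locus at most four alleles may appear, and there must be a
    maternal and a paternal genotype over those alleles such that every typed
    member's genotype takes one allele from each.  Checked by enumerating the
    at most 10 x 10 candidate parent-genotype pairs per locus.
    """
    members = list(group)
    if not members:
        raise ValueError("empty group")
    m = members[0].m
    for l in range(m):
        gs = [ind.genotypes[l] for ind in members]
        gs = [g for g in gs if g is not None]
        if not gs:
            continue
        observed = sorted({a for g in gs for a in g})
        if len(observed) > 4:
            return False
        candidates = list(combinations_with_replacement(observed, 2))
        ok = False
        for mg in candidates:
            for pg in candidates:
                if all(
                    (a in mg and b in pg) or (b in mg and a in pg)
                    for a, b in gs
                ):
                    ok = True
                    break
            if ok:
                break
        if not ok:
            return False
    return True
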