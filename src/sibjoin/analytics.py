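"""Closed-form and enumerative expectations behind the similarity measure.

All quantities assume a single locus with k equally frequent alleles and
diploid Mendelian inheritance.  ``expected_shared_alleles`` gives the exact
expectation of X, the number of alleles two individuals share at one locus
(0 <= X <= 2), for full siblings (shared mother and father), half siblings
(one shared parent) and unrelated pairs.  For unrelated pairs the expectation
has the clean closed form (4k^2 - 4k + 2)/k^3; as k grows the three
expectations tend to 1, 1/2 and 0, which is why shared-allele similarity
separates relationship classes once k or the locus count m is large.  The
Hoeffding bound quantifies the m-dependence: the mean similarity over m
independent loci concentrates exponentially fast.

``triplet_compatibility_fraction`` computes, by exact weighted enumeration,
the probability that three individuals (each two i.i.d. uniform alleles) form
a Mendel-compatible triplet under the half-sibship or the full-sibling
(4-allele + 2-allele) properties — the quantity that explains why triplet
counting is a weak signal for half-sibs: half-sib incompatibilities are rare.
"""
from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache
from itertools import combinations_with_replacement, product

from sympy.utilities.iterables import multiset_partitions

from . import mendel
from .population import Individual

RELATIONSHIPS = ("full", "half", "unrelated")


def _falling(k: int, b: int) -> int:
    out = 1
    for i in range(b):
        out *= k - i
    return out


def _shared(c1: tuple[int, int], c2: tuple[int, int]) -> int:
    count = 0
    rest = list(c2)
    for a in c1:
        if a in rest:
            rest.remove(a)
            count += 1
    return count


def _pattern_expectation(k: int, slots: int, children_of) -> Fraction:
    """Exact E[X] by enumerating equality patterns of i.i.d. uniform draws.

    ``children_of(labels)`` maps a slot->allele-label assignment to the list
    of (child1, child2) outcomes (equally likely inheritance choices).  A
    pattern (set partition of the slots) with b blocks has probability
    k(k-1)...(k-b+1)/k^slots, so the sum is exact for any k and cheap even
    for k ~ 1e6.
    """
    total = Fraction(0)
    for part in multiset_partitions(list(range(slots))):
        b = len(part)
        if b > k:
            continue
        labels = [0] * slots
        for lab, block in enumerate(part):
            for s in block:
                labels[s] = lab
        outcomes = children_of(labels)
        mean = Fraction(sum(_shared(c1, c2) for c1, c2 in outcomes), len(outcomes))
        total += Fraction(_falling(k, b), k**slots) * mean
    return total


def _full_outcomes(lab):
    M, F = (lab[0], lab[1]), (lab[2], lab[3])
    return [
        ((M[a], F[b]), (M[c], F[d]))
        for a, b, c, d in product(range(2), repeat=4)
    ]


def _half_outcomes(lab):
    S, O1, O2 = (lab[0], lab[1]), (lab[2], lab[3]), (lab[4], lab[5])
    return [
        ((S[a], O1[b]), (S[c], O2[d]))
        for a, b, c, d in product(range(2), repeat=4)
    ]


def _unrelated_outcomes(lab):
    return [((lab[0], lab[1]), (lab[2], lab[3]))]


def expected_shared_alleles_exact(relationship: str, k: int) -> Fraction:
    """Exact rational E[X | relationship] for a k-allele locus."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if relationship == "full":
        return _pattern_expectation(k, 4, _full_outcomes)
    if relationship == "half":
        return _pattern_expectation(k, 6, _half_outcomes)
    if relationship == "unrelated":
        return _pattern_expectation(k, 4, _unrelated_outcomes)
    raise ValueError(f"unknown relationship {relationship!r}")


def expected_shared_alleles(relationship: str, k: int) -> float:
    """E[X | relationship] at a k-allele locus (uniform allele frequencies)."""
    return float(expected_shared_alleles_exact(relationship, k))


def unrelated_closed_form(k: int) -> Fraction:
    """(4k^2 - 4k + 2) / k^3, the closed form for unrelated pairs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return Fraction(4 * k * k - 4 * k + 2, k**3)


def hoeffding_deviation_bound(t: float, m: int) -> float:
    """P(|mean similarity - E| >= t) <= 2 exp(-t^2 m / 2) for m i.i.d. loci.

    Follows from Hoeffding's inequality with per-locus similarity bounded in
    [0, 2].
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 2.0 * math.exp(-t * t * m / 2.0)


def _canonical(trip: tuple[tuple[int, int], ...]) -> tuple[tuple[int, int], ...]:
    """Relabel alleles by first appearance so the predicate cache is shared
    across k."""
    relabel: dict[int, int] = {}
    out = []
    for g in trip:
        pair = []
        for a in g:
            if a not in relabel:
                relabel[a] = len(relabel)
            pair.append(relabel[a])
        out.append((pair[0], pair[1]) if pair[0] <= pair[1] else (pair[1], pair[0]))
    return tuple(out)


@lru_cache(maxsize=None)
def _triplet_compatible(canon: tuple[tuple[int, int], ...], relationship: str) -> bool:
    group = [Individual(str(i), (g,)) for i, g in enumerate(canon)]
    if relationship == "half":
        return mendel.half_sib_compatible(group)
    return mendel.full_sib_compatible(group)


def triplet_compatibility_fraction_exact(relationship: str, k: int) -> Fraction:
    """Exact P(compatible triplet) under two i.i.d. uniform alleles each.

    Enumerates unordered genotypes weighted by their sampling probability
    (heterozygote 2/k^2, homozygote 1/k^2) over all multisets of three,
    delegating compatibility to the shared Mendelian predicates.
    """
    if relationship not in ("full", "half"):
        raise ValueError(f"relationship must be 'full' or 'half', got {relationship!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    genos = [(a, b) for a in range(k) for b in range(a, k)]
    weight = {g: (1 if g[0] == g[1] else 2) for g in genos}
    hit = Fraction(0)
    denom = Fraction(k**6)
    for trip in combinations_with_replacement(genos, 3):
        # ordered arrangements of this multiset
        mult = {}
        for g in trip:
            mult[g] = mult.get(g, 0) + 1
        perms = 6
        for c in mult.values():
            perms //= math.factorial(c)
        w = perms * weight[trip[0]] * weight[trip[1]] * weight[trip[2]]
        if _triplet_compatible(_canonical(trip), relationship):
            hit += Fraction(w, 1)
    return hit / denom


def triplet_compatibility_fraction(relationship: str, k: int) -> float:
    """P(random triplet is Mendel-compatible) under the stated relationship."""
    return float(triplet_compatibility_fraction_exact(relationship, k))
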