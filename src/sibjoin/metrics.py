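"""Accuracy metrics for sibship reconstructions.

Variation of information (VI) between two partitions P, Q of n items is
H(P) + H(Q) - 2 I(P, Q) under the empirical joint block-membership
distribution; it is a metric, zero iff the partitions are identical, and at
most log n.  Natural logarithms are used throughout; the base cancels in the
normalized half-sib score.

The half-sib score (HSVI) compares a reconstructed (M', P') against the true
(M, P).  Because the sex of the common parent is unidentifiable, both sex
pairings are evaluated and the better one kept:

    HSVI = min( (VI(M,M') + VI(P,P'))/2 , (VI(M,P') + VI(P,M'))/2 ) / log n

Partition distance is the minimum number of individuals whose removal makes
two partitions identical: n minus the maximum-weight matching of blocks
weighted by intersection size.
"""
from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

Partitioning = Sequence[frozenset[str]]


def _check(P: Partitioning, Q: Partitioning) -> frozenset[str]:
    uP = frozenset().union(*P) if P else frozenset()
    uQ = frozenset().union(*Q) if Q else frozenset()
    if uP != uQ:
        raise ValueError("partitions cover different universes")
    if sum(len(b) for b in P) != len(uP) or sum(len(b) for b in Q) != len(uQ):
        raise ValueError("blocks overlap")
    return uP


def as_blocks(blocks: Iterable[Iterable[str]]) -> list[frozenset[str]]:
    return [frozenset(b) for b in blocks if b]


def vi(P: Partitioning, Q: Partitioning) -> float:
    """Variation of information, in nats."""
    universe = _check(P, Q)
    n = len(universe)
    if n == 0:
        raise ValueError("empty universe")
    hP = -sum((len(b) / n) * math.log(len(b) / n) for b in P)
    hQ = -sum((len(b) / n) * math.log(len(b) / n) for b in Q)
    mi = 0.0
    for bp in P:
        for bq in Q:
            x = len(bp & bq)
            if x:
                mi += (x / n) * math.log(x * n / (len(bp) * len(bq)))
    return max(hP + hQ - 2.0 * mi, 0.0)


def hsvi(
    truth_maternal: Partitioning,
    truth_paternal: Partitioning,
    inferred_maternal: Partitioning,
    inferred_paternal: Partitioning,
) -> float:
    """Normalized half-sib VI in [0, 1]; 0 is a perfect reconstruction.

    The min over the two sex pairings makes the score invariant to swapping
    the inferred maternal/paternal labels.
    """
    n = len(_check(truth_maternal, inferred_maternal))
    _check(truth_paternal, inferred_paternal)
    straight = (
        vi(truth_maternal, inferred_maternal) + vi(truth_paternal, inferred_paternal)
    ) / 2.0
    crossed = (
        vi(truth_maternal, inferred_paternal) + vi(truth_paternal, inferred_maternal)
    ) / 2.0
    best = min(straight, crossed)
    if n < 2:
        if best == 0.0:
            return 0.0
        raise ValueError("HSVI undefined for n < 2 unless partitions are identical")
    return best / math.log(n)


def _overlap_matrix(P: Partitioning, Q: Partitioning) -> np.ndarray:
    W = np.zeros((len(P), len(Q)), dtype=np.int64)
    for i, bp in enumerate(P):
        for j, bq in enumerate(Q):
            W[i, j] = len(bp & bq)
    return W


def partition_distance(P: Partitioning, Q: Partitioning) -> int:
    """Minimum removals making P and Q identical (assignment formulation)."""
    universe = _check(P, Q)
    W = _overlap_matrix(P, Q)
    r, c = linear_sum_assignment(W, maximize=True)
    return len(universe) - int(W[r, c].sum())


def matched_individuals(P: Partitioning, Q: Partitioning) -> frozenset[str]:
    """Individuals kept by the maximum-overlap block matching of P onto Q."""
    _check(P, Q)
    W = _overlap_matrix(P, Q)
    r, c = linear_sum_assignment(W, maximize=True)
    kept: set[str] = set()
    for i, j in zip(r, c):
        kept |= P[i] & Q[j]
    return frozenset(kept)


def misplaced_individuals(
    truth_maternal: Partitioning,
    truth_paternal: Partitioning,
    inferred_maternal: Partitioning,
    inferred_paternal: Partitioning,
) -> frozenset[str]:
    """Individuals not preserved by the best block matching on either side.

    The sex pairing is the one HSVI selects; the result is the union over
    both sides of the individuals outside the matched block intersections
    (the "false positives" of a reconstruction).
    """
    universe = _check(truth_maternal, inferred_maternal)
    straight = (
        vi(truth_maternal, inferred_maternal) + vi(truth_paternal, inferred_paternal)
    )
    crossed = (
        vi(truth_maternal, inferred_paternal) + vi(truth_paternal, inferred_maternal)
    )
    if crossed < straight:
        inferred_maternal, inferred_paternal = inferred_paternal, inferred_maternal
    kept = matched_individuals(
        list(truth_maternal), list(inferred_maternal)
    ) & matched_individuals(list(truth_paternal), list(inferred_paternal))
    return frozenset(universe - kept)
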