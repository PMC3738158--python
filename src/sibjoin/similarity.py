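"""Pairwise shared-allele similarity.

For two individuals the similarity s_xy is the sum over loci of the multiset
intersection of their genotypes, so comparing homozygotes (2,2) vs (2,2)
contributes 2 at that locus while (1,2) vs (1,1) contributes 1.  Loci where
either individual dropped out contribute 0.  The n x n matrix of these counts
is what drives the clustering heuristic; it costs O(n^2 m) to build.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .population import Individual, Population


def pair_similarity(x: Individual, y: Individual) -> int:
    """Shared-allele count s_xy, summed over loci (dropout loci count 0)."""
    if x.m != y.m:
        raise ValueError(f"locus count mismatch: {x.m} vs {y.m}")
    total = 0
    for g, h in zip(x.genotypes, y.genotypes):
        if g is None or h is None:
            continue
        total += _multiset_shared(g, h)
    return total


def _multiset_shared(g: tuple[int, int], h: tuple[int, int]) -> int:
    """Multiset intersection cardinality of two allele pairs."""
    count = 0
    remaining = list(h)
    for a in g:
        if a in remaining:
            remaining.remove(a)
            count += 1
    return count


def similarity_matrix(pop: Population) -> np.ndarray:
    """The symmetric n x n matrix of pair similarities.

    The diagonal holds self-similarity, 2 x (number of typed loci).
    """
    n = pop.n
    S = np.zeros((n, n), dtype=np.int64)
    inds = pop.individuals
    for i in range(n):
        S[i, i] = 2 * inds[i].n_typed_loci()
        for j in range(i + 1, n):
            s = pair_similarity(inds[i], inds[j])
            S[i, j] = S[j, i] = s
    return S


def write_similarity_tsv(pop: Population, S: np.ndarray, path: str | Path) -> None:
    """Export the similarity matrix as TSV with ids as header row/column."""
    ids = [ind.id for ind in pop.individuals]
    with Path(path).open("w") as fh:
        fh.write("\t".join(["id"] + ids) + "\n")
        for i, iid in enumerate(ids):
            fh.write("\t".join([iid] + [str(int(v)) for v in S[i]]) + "\n")
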