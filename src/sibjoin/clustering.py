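"""The SibJoin heuristic: constrained agglomerative half-sib clustering.

The algorithm starts with 2n singleton clusters — every individual seeds one
cluster on each parental side — and agglomerates under Mendelian
constraints.  Three checks guard every merge:

* the merged cluster's feasible-parent set stays non-empty at every locus
  (half-sibship property, maintained incrementally by set intersection);
* the cluster graph stays bipartite.  The graph has one vertex per live
  cluster and, for every individual, an edge between its two clusters; its
  two-coloring is what lets "maternal" and "paternal" stay fluid while still
  guaranteeing one parent of each sex per individual;
* every implied full-sib family (intersection of two adjacent clusters)
  satisfies the 4-allele and 2-allele properties.

Cluster similarity is single linkage: sim(Ci, Cj) = max s_xy over cross
pairs.  The schedule sweeps a similarity threshold s from 2m down to 1; at
level s every pair with similarity >= s is a candidate, attempted in order
of descending similarity, with joins that create or extend a full-sib
family first at each similarity value (full sibships are the stricter and
therefore safer merge), then ties break toward the largest combined size,
then the smallest member id.  After every successful merge the level is
re-scanned, so joins unlocked by earlier merges — including pairs rejected
at a higher threshold — are retried.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from . import mendel
from .partition import SibPartition, make_partition
from .population import Population
from .similarity import similarity_matrix

logger = logging.getLogger(__name__)

ACCEPT = "accept"
REJECT_EMPTY_PARENT_SET = "empty_parent_set"
REJECT_NOT_BIPARTITE = "not_bipartite"
REJECT_FULL_FAMILY = "incompatible_full_family"


@dataclass
class _Cluster:
    members: set[int]
    parent_set: mendel.ParentSet
    min_id: str  # lexicographically smallest member id, for tie-breaking


class SibJoinState:
    """Mutable clustering state; drives joins and exposes them for testing."""

    def __init__(self, pop: Population):
        self.pop = pop
        self.allele_sets = pop.allele_sets()
        self.S = similarity_matrix(pop)
        n = pop.n
        self.clusters: dict[int, _Cluster] = {}
        # individual -> its two cluster ids (side labels stay fluid)
        self.ind_clusters: list[list[int]] = []
        for i, ind in enumerate(pop.individuals):
            ps = mendel.initial_parent_set(ind, self.allele_sets)
            self.clusters[2 * i] = _Cluster({i}, ps, ind.id)
            self.clusters[2 * i + 1] = _Cluster({i}, ps, ind.id)
            self.ind_clusters.append([2 * i, 2 * i + 1])
        # single-linkage similarity per cluster pair; -1 marks the two
        # clusters of one individual, whose only cross pair is (x, x)
        self.sims: dict[tuple[int, int], int] = {}
        for i in range(n):
            self.sims[(2 * i, 2 * i + 1)] = -1
            for j in range(i + 1, n):
                s = int(self.S[i, j])
                for a in (2 * i, 2 * i + 1):
                    for b in (2 * j, 2 * j + 1):
                        self.sims[(a, b)] = s

    # -- basic queries ----------------------------------------------------

    def _key(self, ci: int, cj: int) -> tuple[int, int]:
        return (ci, cj) if ci < cj else (cj, ci)

    def cluster_similarity(self, ci: int, cj: int) -> int:
        """Single-linkage similarity: max s_xy over cross pairs x != y.

        Maintained incrementally (merging clusters takes the max); -1 when
        the only cross pairs are an individual with itself.
        """
        return self.sims[self._key(ci, cj)]

    def neighbors(self, ci: int) -> set[int]:
        """Clusters sharing an individual with ci (edges of the cluster graph)."""
        out = set()
        for e in self.clusters[ci].members:
            a, b = self.ind_clusters[e]
            out.add(b if a == ci else a)
        return out

    def _edges(self, relabel: dict[int, int] | None = None) -> list[tuple[int, int]]:
        rl = relabel or {}
        return [
            (rl.get(a, a), rl.get(b, b))
            for a, b in (self.ind_clusters[e] for e in range(self.pop.n))
        ]

    def _is_bipartite(self, relabel: dict[int, int] | None = None) -> bool:
        color: dict[int, int] = {}
        adj: dict[int, set[int]] = {}
        for a, b in self._edges(relabel):
            if a == b:
                return False  # self-loop: odd cycle of length one
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for root in adj:
            if root in color:
                continue
            color[root] = 0
            stack = [root]
            while stack:
                v = stack.pop()
                for w in adj[v]:
                    if w not in color:
                        color[w] = 1 - color[v]
                        stack.append(w)
                    elif color[w] == color[v]:
                        return False
        return True

    # -- the join operation -----------------------------------------------

    def try_join(self, ci: int, cj: int) -> str:
        """Attempt to merge cluster cj into ci; returns ACCEPT or a reason.

        On rejection the state is unchanged.
        """
        if ci == cj:
            raise ValueError("cannot join a cluster with itself")
        if ci not in self.clusters or cj not in self.clusters:
            raise ValueError("joining a dead cluster")
        A, B = self.clusters[ci], self.clusters[cj]

        merged_ps = mendel.intersect_parent_sets(A.parent_set, B.parent_set)
        if not merged_ps.is_feasible():
            return REJECT_EMPTY_PARENT_SET

        if not self._is_bipartite({cj: ci}):
            return REJECT_NOT_BIPARTITE

        # implied full families touching the merged cluster: group its
        # members by their opposite-side cluster
        union = A.members | B.members
        by_other: dict[int, list[int]] = {}
        for e in union:
            a, b = self.ind_clusters[e]
            other = b if (a == ci or a == cj) else a
            if other == ci or other == cj:
                # both clusters of e would collapse into one: self-loop,
                # already excluded by the bipartiteness check
                return REJECT_NOT_BIPARTITE
            by_other.setdefault(other, []).append(e)
        inds = self.pop.individuals
        for fam in by_other.values():
            if len(fam) > 1 and not mendel.full_sib_compatible(
                [inds[e] for e in fam], self.allele_sets
            ):
                return REJECT_FULL_FAMILY

        # commit
        A.members = union
        A.parent_set = merged_ps
        A.min_id = min(A.min_id, B.min_id)
        for e in B.members:
            pair = self.ind_clusters[e]
            pair[pair.index(cj)] = ci
        del self.clusters[cj]
        for ck in list(self.clusters):
            if ck == ci:
                continue
            ka = self._key(ci, ck)
            kb = self._key(cj, ck)
            self.sims[ka] = max(self.sims[ka], self.sims.pop(kb))
        self.sims.pop(self._key(ci, cj), None)
        return ACCEPT

    # -- the schedule -------------------------------------------------------

    def _candidates(self, level: int) -> list[tuple[int, int]]:
        """Joinable pairs at this similarity level, in attempt order."""
        nbrs = {c: self.neighbors(c) for c in self.clusters}
        cands = []
        for (a, b), s in self.sims.items():
            if s < level:
                continue
            ca, cb = self.clusters[a], self.clusters[b]
            forms_full = bool((nbrs[a] & nbrs[b]) - {a, b})
            size = len(ca.members) + len(cb.members)
            cands.append(
                ((-s, not forms_full, -size, min(ca.min_id, cb.min_id), a, b), (a, b))
            )
        cands.sort()
        return [pair for _, pair in cands]

    def run(self) -> None:
        for level in range(2 * self.pop.m, 0, -1):
            while True:
                joined = False
                for a, b in self._candidates(level):
                    if a not in self.clusters or b not in self.clusters:
                        continue
                    if self.try_join(a, b) == ACCEPT:
                        joined = True
                        break
                if not joined:
                    break

    # -- output --------------------------------------------------------------

    def to_partition(self, mode: str = "both") -> SibPartition:
        """Two-color the cluster graph and emit the two partitions.

        Components are colored independently (root = smallest live cluster
        id, colored maternal); in ``single`` mode the side with the larger
        mean cluster size is reported as maternal, since a single
        reconstructed sex should be the better-resolved one.
        """
        adj: dict[int, set[int]] = {c: set() for c in self.clusters}
        for a, b in self._edges():
            adj[a].add(b)
            adj[b].add(a)
        color: dict[int, int] = {}
        for root in sorted(adj):
            if root in color:
                continue
            color[root] = 0
            stack = [root]
            while stack:
                v = stack.pop()
                for w in sorted(adj[v]):
                    if w not in color:
                        color[w] = 1 - color[v]
                        stack.append(w)
                    elif color[w] == color[v]:
                        raise AssertionError("cluster graph lost bipartiteness")
        ids = [ind.id for ind in self.pop.individuals]
        side0 = [
            sorted(ids[e] for e in self.clusters[c].members)
            for c in sorted(self.clusters)
            if color[c] == 0
        ]
        side1 = [
            sorted(ids[e] for e in self.clusters[c].members)
            for c in sorted(self.clusters)
            if color[c] == 1
        ]
        if mode == "single":
            mean0 = sum(map(len, side0)) / max(len(side0), 1)
            mean1 = sum(map(len, side1)) / max(len(side1), 1)
            if mean1 > mean0:
                side0, side1 = side1, side0
        return make_partition(side0, side1)


def run_sibjoin(pop: Population, mode: str = "both", seed: int = 0) -> SibPartition:
    """Reconstruct maternal and paternal half-sib partitions.

    ``mode`` is ``"both"`` (default) or ``"single"`` (report the
    better-resolved side first, for populations where only one sex is
    polygamous or only one truth partition is known).  The algorithm is
    deterministic given the population order; ``seed`` is accepted for
    interface stability but unused.
    """
    if pop.n == 0:
        raise ValueError("empty population")
    if mode not in ("both", "single"):
        raise ValueError(f"unknown mode {mode!r}")
    state = SibJoinState(pop)
    state.run()
    part = state.to_partition(mode)
    logger.info(
        "sibjoin: n=%d m=%d -> %d maternal / %d paternal clusters",
        pop.n, pop.m, len(part.maternal), len(part.paternal),
    )
    return part


def audit_partition(pop: Population, part: SibPartition) -> list[str]:
    """Exhaustive validity audit of a reconstruction; returns violations.

    Checks that each individual is in exactly one cluster per side, that
    every cluster is half-sib compatible, and that every implied full family
    is full-sib compatible.
    """
    problems = []
    by_id = pop.by_id()
    if part.universe != frozenset(by_id):
        problems.append("partition universe differs from population")
        return problems
    allele_sets = pop.allele_sets()
    for label, side in (("maternal", part.maternal), ("paternal", part.paternal)):
        for block in side:
            if not mendel.half_sib_compatible(
                [by_id[i] for i in block], allele_sets
            ):
                problems.append(f"{label} cluster {sorted(block)} not half-sib compatible")
    for fam in part.full_families():
        if not mendel.full_sib_compatible([by_id[i] for i in fam], allele_sets):
            problems.append(f"full family {sorted(fam)} not full-sib compatible")
    return problems
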