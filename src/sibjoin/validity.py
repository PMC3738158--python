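"""Minimum-removal Mendelian validation of a proposed half-sib partitioning.

Deciding whether a maternal + paternal half-sib partitioning of a polygamous
population admits consistent parental genotypes is NP-complete, so instead of
a yes/no check this module solves the parsimony variant as a 0/1 integer
program: remove the fewest individuals so that every family can be assigned a
shared-parent genotype and every remaining child inherits one allele from
each of its two parents.

Variables, with C the multiset of maternal and paternal families, pi0/pi1
the child -> family maps, lambda0/lambda1 the child-allele -> allele-index
maps and K the locus allele set:

* x_i        — remove individual i;
* y_{j,k}^l  — family j's shared parent carries allele k at locus l;
* x_{0,i}^l, x_{1,i}^l — the two inheritance orientations of child i's
  allele pair fail at locus l;
* x_i^l      — locus l is incompatible for child i.

Constraints: each parent carries at most two alleles
(sum_k y_{j,k}^l <= 2); each orientation is satisfied or flagged
(x_{0,i}^l + (y_{pi0(i),lam0(i)}^l + y_{pi1(i),lam1(i)}^l)/2 >= 1 and the
mirrored version); both orientations failing marks the locus
(x_{0,i}^l + x_{1,i}^l - x_i^l <= 1); an incompatible locus forces removal
(x_i - x_i^l >= 0).  The objective minimizes the number of removals; the
program has O(m n) constraints.  Dropout loci generate no orientation
constraints.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .partition import SibPartition
from .population import Genotype, Population

DEFAULT_TIME_LIMIT = 300.0  # seconds


@dataclass(frozen=True)
class RemovalProblem:
    """A population, its families C, and the index maps of the program."""

    pop: Population
    families: tuple[tuple[int, ...], ...]  # members as individual indices
    family_labels: tuple[str, ...]
    pi0: tuple[int, ...]  # individual -> maternal family index in C
    pi1: tuple[int, ...]  # individual -> paternal family index in C
    alleles: tuple[tuple[int, ...], ...]  # per-locus allele set K_l

    @property
    def n(self) -> int:
        return self.pop.n

    @property
    def m(self) -> int:
        return self.pop.m

    def allele_index(self, l: int, allele: int) -> int:
        return self.alleles[l].index(allele)


def build_removal_problem(pop: Population, partition: SibPartition) -> RemovalProblem:
    """Index the families of a candidate partitioning for the IP."""
    if partition.universe != frozenset(ind.id for ind in pop.individuals):
        raise ValueError("partition does not cover the population")
    idx = {ind.id: i for i, ind in enumerate(pop.individuals)}
    families: list[tuple[int, ...]] = []
    labels: list[str] = []
    pi0 = [-1] * pop.n
    pi1 = [-1] * pop.n
    for j, block in enumerate(partition.maternal):
        fam = tuple(sorted(idx[i] for i in block))
        families.append(fam)
        labels.append(f"M{j}")
        for e in fam:
            pi0[e] = len(families) - 1
    for j, block in enumerate(partition.paternal):
        fam = tuple(sorted(idx[i] for i in block))
        families.append(fam)
        labels.append(f"P{j}")
        for e in fam:
            pi1[e] = len(families) - 1
    return RemovalProblem(
        pop,
        tuple(families),
        tuple(labels),
        tuple(pi0),
        tuple(pi1),
        tuple(pop.allele_sets()),
    )


@dataclass
class IPModel:
    """The assembled 0/1 program, ready for an exact MILP solver."""

    problem: RemovalProblem
    c: np.ndarray
    A: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    n_vars: int
    y_index: dict[tuple[int, int, int], int]  # (family j, locus l, allele idx)
    aux_index: dict[tuple[str, int, int], int]  # ("x0"|"x1"|"xl", i, l)

    @property
    def n_constraints(self) -> int:
        return self.A.shape[0]


def build_ip(problem: RemovalProblem) -> IPModel:
    """Assemble the five constraint families exactly as displayed."""
    n, m = problem.n, problem.m
    nfam = len(problem.families)
    col = n  # x_i occupy columns 0..n-1
    y_index: dict[tuple[int, int, int], int] = {}
    for j in range(nfam):
        for l in range(m):
            for ki in range(len(problem.alleles[l])):
                y_index[(j, l, ki)] = col
                col += 1
    aux_index: dict[tuple[str, int, int], int] = {}
    typed = [
        (i, l)
        for i, ind in enumerate(problem.pop.individuals)
        for l in range(m)
        if ind.genotypes[l] is not None
    ]
    for i, l in typed:
        for tag in ("x0", "x1", "xl"):
            aux_index[(tag, i, l)] = col
            col += 1
    n_vars = col

    rows, cols, data, lbs, ubs = [], [], [], [], []
    r = 0

    def add(entries, lo, hi):
        nonlocal r
        for cc, v in entries:
            rows.append(r)
            cols.append(cc)
            data.append(v)
        lbs.append(lo)
        ubs.append(hi)
        r += 1

    # (1) a shared parent carries at most two alleles
    for j in range(nfam):
        for l in range(m):
            add(
                [(y_index[(j, l, ki)], 1.0) for ki in range(len(problem.alleles[l]))],
                -np.inf,
                2.0,
            )
    # (2),(3) the two inheritance orientations; (4),(5) failure bookkeeping
    for i, l in typed:
        a, b = problem.pop.individuals[i].genotypes[l]
        la = problem.allele_index(l, a)
        lb_ = problem.allele_index(l, b)
        jm, jp = problem.pi0[i], problem.pi1[i]
        x0 = aux_index[("x0", i, l)]
        x1 = aux_index[("x1", i, l)]
        xl = aux_index[("xl", i, l)]
        add(
            [(x0, 1.0), (y_index[(jm, l, la)], 0.5), (y_index[(jp, l, lb_)], 0.5)],
            1.0,
            np.inf,
        )
        add(
            [(x1, 1.0), (y_index[(jm, l, lb_)], 0.5), (y_index[(jp, l, la)], 0.5)],
            1.0,
            np.inf,
        )
        add([(x0, 1.0), (x1, 1.0), (xl, -1.0)], -np.inf, 1.0)
        add([(i, 1.0), (xl, -1.0)], 0.0, np.inf)

    c = np.zeros(n_vars)
    c[:n] = 1.0
    A = sparse.csr_matrix(
        (data, (rows, cols)), shape=(r, n_vars)
    )
    return IPModel(
        problem, c, A, np.array(lbs), np.array(ubs), n_vars, y_index, aux_index
    )


@dataclass(frozen=True)
class RemovalSolution:
    removed_ids: frozenset[str]
    parent_genotypes: tuple[tuple[Genotype, ...], ...]  # per family, per locus
    objective: int
    status: str  # "optimal" or "time-limited"
    gap: float | None = None

    @property
    def removed_count(self) -> int:
        return len(self.removed_ids)


def _genotypes_from_y(model: IPModel, x: np.ndarray):
    problem = model.problem
    out = []
    for j in range(len(problem.families)):
        per_locus: list[Genotype] = []
        for l in range(problem.m):
            carried = [
                problem.alleles[l][ki]
                for ki in range(len(problem.alleles[l]))
                if x[model.y_index[(j, l, ki)]] > 0.5
            ]
            if not carried:
                per_locus.append(None)
            elif len(carried) == 1:
                per_locus.append((carried[0], carried[0]))
            else:
                per_locus.append((min(carried), max(carried)))
        out.append(tuple(per_locus))
    return tuple(out)


def solve_min_removal(
    model: IPModel | RemovalProblem, time_limit: float = DEFAULT_TIME_LIMIT
) -> RemovalSolution:
    """Solve the 0/1 program exactly (HiGHS), honoring a wall-clock limit."""
    if isinstance(model, RemovalProblem):
        model = build_ip(model)
    res = milp(
        model.c,
        constraints=LinearConstraint(model.A, model.lb, model.ub),
        integrality=np.ones(model.n_vars),
        bounds=Bounds(0.0, 1.0),
        options={"time_limit": float(time_limit)},
    )
    if res.x is None:
        # removing every individual is always feasible, so this can only be
        # a solver failure, not genuine infeasibility
        raise RuntimeError(f"MILP solver returned no incumbent: {res.message}")
    x = np.round(res.x)
    removed = frozenset(
        model.problem.pop.individuals[i].id
        for i in range(model.problem.n)
        if x[i] > 0.5
    )
    gap = getattr(res, "mip_gap", None)
    status = "optimal" if res.status == 0 else "time-limited"
    return RemovalSolution(
        removed_ids=removed,
        parent_genotypes=_genotypes_from_y(model, x),
        objective=int(round(sum(x[: model.problem.n]))),
        status=status,
        gap=None if gap is None else float(gap),
    )


def verify_assignment(
    problem: RemovalProblem,
    parent_genotypes,
    ignore: frozenset[str] = frozenset(),
) -> list[tuple[str, int, str]]:
    """Polynomial-time certificate check of a parental genotype assignment.

    A child is consistent at a locus iff its allele pair can be oriented so
    that each parent's genotype contains the allele attributed to it — the
    forced-allele rule: a parent whose genotype differs from the child's
    forces which allele the child took from it, while an identical parent
    genotype forces nothing.  Returns (individual id, locus, reason)
    violations; an empty list certifies validity.
    """
    violations = []
    for i, ind in enumerate(problem.pop.individuals):
        if ind.id in ignore:
            continue
        for l, g in enumerate(ind.genotypes):
            if g is None:
                continue
            gm = parent_genotypes[problem.pi0[i]][l]
            gp = parent_genotypes[problem.pi1[i]][l]
            a, b = g
            ok = False
            for p, q in ((a, b), (b, a)):
                m_ok = gm is None or p in gm
                p_ok = gp is None or q in gp
                if m_ok and p_ok:
                    ok = True
                    break
            if not ok:
                violations.append(
                    (ind.id, l, f"alleles {g} not explainable by {gm} x {gp}")
                )
    return violations


# -- brute-force oracle ------------------------------------------------------


def _locus_feasible(problem: RemovalProblem, kept: set[int], l: int) -> bool:
    """Backtracking search for consistent parent genotypes at one locus."""
    children = [
        (i, problem.pop.individuals[i].genotypes[l])
        for i in sorted(kept)
        if problem.pop.individuals[i].genotypes[l] is not None
    ]
    if not children:
        return True
    fam_children: dict[int, list[int]] = {}
    for i, _ in children:
        fam_children.setdefault(problem.pi0[i], []).append(i)
        fam_children.setdefault(problem.pi1[i], []).append(i)
    fams = sorted(fam_children, key=lambda j: -len(fam_children[j]))
    order = {j: t for t, j in enumerate(fams)}
    # candidate genotypes per family: WLOG pairs over its children's alleles
    candidates: dict[int, list[tuple[int, int]]] = {}
    for j in fams:
        alleles = sorted(
            {
                a
                for i in fam_children[j]
                for a in problem.pop.individuals[i].genotypes[l]
            }
        )
        candidates[j] = list(combinations_with_replacement(alleles, 2))
    geno = dict.fromkeys(fams)
    child_geno = {i: g for i, g in children}

    def consistent(i: int) -> bool:
        gm = geno[problem.pi0[i]]
        gp = geno[problem.pi1[i]]
        a, b = child_geno[i]
        return any(p in gm and q in gp for p, q in ((a, b), (b, a)))

    def backtrack(t: int) -> bool:
        if t == len(fams):
            return True
        j = fams[t]
        for cand in candidates[j]:
            geno[j] = cand
            if all(
                consistent(i)
                for i in fam_children[j]
                if order[problem.pi0[i]] <= t and order[problem.pi1[i]] <= t
            ):
                if backtrack(t + 1):
                    return True
        geno[j] = None
        return False

    return backtrack(0)


def brute_force_min_removal(
    problem: RemovalProblem, max_individuals: int = 12
) -> RemovalSolution:
    """Exact minimum by exhaustive search over removal subsets, small n only.

    Loci are checked independently (they share only the removal set), each by
    backtracking over family genotype assignments.
    """
    n = problem.n
    if n > max_individuals:
        raise ValueError(
            f"brute force limited to {max_individuals} individuals, got {n}"
        )

    def feasible(kept: set[int]) -> bool:
        return all(_locus_feasible(problem, kept, l) for l in range(problem.m))

    for r in range(n + 1):
        for removed in combinations(range(n), r):
            kept = set(range(n)) - set(removed)
            if feasible(kept):
                ids = frozenset(
                    problem.pop.individuals[i].id for i in removed
                )
                return RemovalSolution(
                    removed_ids=ids,
                    parent_genotypes=tuple(
                        tuple(None for _ in range(problem.m))
                        for _ in problem.families
                    ),
                    objective=r,
                    status="optimal",
                    gap=0.0,
                )
    raise AssertionError("unreachable: removing everyone is always feasible")
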