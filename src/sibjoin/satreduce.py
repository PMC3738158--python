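"""MONOTONE ONE-IN-THREE SAT -> valid half-sibling partitioning reduction.

The reduction that proves NP-completeness of the half-sib validity decision
doubles as an adversarial instance generator.  Every literal x_i maps to a
unique allele y_i; each clause c_p contributes a fresh allele s_p; one extra
allele z is shared by all clause gadgets.  Three gadgets build a single-locus
population plus a maternal/paternal partitioning:

* selection — per clause (x_i | x_j | x_k), one maternal family with six
  children, two copies each of (y_i,y_j), (y_i,y_k), (y_j,y_k).  The family's
  shared mother must pick two of the three alleles; the allele she does NOT
  carry is the literal set true.
* mapping — six paternal families per clause, one per selection child, each
  also containing copies of (s_p, y_a), an (s_p, z) child and a (y_b, z)
  child.  The father's genotype choice ((s_p, y_b) vs (y_a, z)) transmits the
  selection decision onto the s_p alleles.
* enforcement — for every pair of clauses (c_p, c_q) sharing a variable x_a,
  a maternal family over two copies each of (s_p, y_a) and (s_q, y_a) plus
  fresh (s_p, z), (s_q, z) children, forcing x_a's truth value to agree
  across clauses.

Individuals appearing in only one gadget get a singleton family on their
unassigned side.  The instance is one-in-three satisfiable iff the produced
partitioning is Mendel-valid, i.e. iff the minimum-removal IP objective is 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

from .partition import SibPartition, make_partition
from .population import Genotype, Individual, Population
from .validity import RemovalProblem, build_removal_problem, verify_assignment


@dataclass(frozen=True)
class SatInstance:
    """Monotone clauses of exactly three distinct positive literals."""

    variables: tuple[str, ...]
    clauses: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        for cl in self.clauses:
            if len(cl) != 3:
                raise ValueError(f"clause {sorted(cl)} must have 3 distinct literals")
            if not cl <= set(self.variables):
                raise ValueError(f"clause {sorted(cl)} uses unknown literals")


def make_instance(clauses: Iterable[Iterable[str]]) -> SatInstance:
    cls = tuple(frozenset(map(str, cl)) for cl in clauses)
    variables = tuple(sorted({v for cl in cls for v in cl}))
    return SatInstance(variables, cls)


def one_in_three_satisfiable(instance: SatInstance):
    """Brute-force search; returns a satisfying set of true variables or None."""
    nv = len(instance.variables)
    for bits in product((False, True), repeat=nv):
        true = {v for v, b in zip(instance.variables, bits) if b}
        if all(len(cl & true) == 1 for cl in instance.clauses):
            return frozenset(true)
    return None


@dataclass(frozen=True)
class ReductionOutput:
    instance: SatInstance
    pop: Population
    partition: SibPartition
    literal_allele: Mapping[str, int]  # f: literal -> y allele
    clause_alleles: tuple[int, ...]  # s_0 .. s_{m-1}
    z_allele: int
    selection_families: tuple[frozenset[str], ...]  # one per clause, in order


def reduce_sat(instance: SatInstance) -> ReductionOutput:
    """Build the single-locus population and partitioning for an instance."""
    nv = len(instance.variables)
    nc = len(instance.clauses)
    y = {v: i + 1 for i, v in enumerate(instance.variables)}
    s = tuple(nv + 1 + p for p in range(nc))
    z = nv + nc + 2

    genotypes: dict[str, tuple[int, int]] = {}
    maternal: dict[str, list[str]] = {}
    paternal: dict[str, list[str]] = {}

    def child(name: str, a: int, b: int) -> str:
        if name in genotypes:
            raise AssertionError(f"duplicate individual {name}")
        genotypes[name] = (a, b) if a <= b else (b, a)
        return name

    # clause sets per variable, for copy counts and enforcement pairs
    occurs: dict[str, list[int]] = {v: [] for v in instance.variables}
    for p, cl in enumerate(instance.clauses):
        for v in cl:
            occurs[v].append(p)

    # selection gadget: one maternal family of six per clause
    selection: list[list[str]] = []
    sel_child: dict[tuple[int, str, str], str] = {}  # (clause, low var, high var) pair copies
    for p, cl in enumerate(instance.clauses):
        lits = sorted(cl, key=lambda v: y[v])
        fam = []
        for u, v in combinations(lits, 2):
            for c in range(2):
                name = child(f"c{p}:sel({y[u]},{y[v]}):{c}", y[u], y[v])
                fam.append(name)
                sel_child[(p, u, v, c)] = name
        maternal[f"sel{p}"] = fam
        selection.append(fam)

    # mapping gadget: six paternal families per clause; copies of (s_p, y_a)
    # feed the enforcement gadget
    copies: dict[tuple[int, str], list[list[str]]] = {}
    for p, cl in enumerate(instance.clauses):
        lits = sorted(cl, key=lambda v: y[v])
        i, j, k = lits
        # (variable a, partner b, selection-child copy index)
        columns = [
            (i, j, 0), (i, k, 0), (j, i, 1), (j, k, 0), (k, i, 1), (k, j, 1)
        ]
        seen_var: dict[str, int] = {}
        for a, b, copy_idx in columns:
            side = seen_var.get(a, 0)
            seen_var[a] = side + 1
            u, v = (a, b) if y[a] < y[b] else (b, a)
            fam = [sel_child[(p, u, v, copy_idx)]]
            ncopies = max(1, len(occurs[a]) - 1)
            col_copies = []
            for t in range(ncopies):
                name = child(
                    f"c{p}:map(s{p},{y[a]}):{side}.{t}", s[p], y[a]
                )
                col_copies.append(name)
                fam.append(name)
            copies.setdefault((p, a), [[], []])[side] = col_copies
            fam.append(child(f"c{p}:map(s{p},z):{a}.{b}", s[p], z))
            fam.append(child(f"c{p}:map({y[b]},z):{a}", y[b], z))
            paternal[f"map{p}:{a}:{side}"] = fam

    # enforcement gadget: one maternal family per clause pair sharing a variable
    used: dict[str, int] = {}
    for v in instance.variables:
        cls = occurs[v]
        consumed = {p: [0, 0] for p in cls}
        for p, q in combinations(sorted(cls), 2):
            fam = []
            for clause in (p, q):
                for side in range(2):
                    t = consumed[clause][side]
                    consumed[clause][side] += 1
                    fam.append(copies[(clause, v)][side][t])
            fam.append(child(f"enf({v}):{p}.{q}:s{p}z", s[p], z))
            fam.append(child(f"enf({v}):{p}.{q}:s{q}z", s[q], z))
            maternal[f"enf:{v}:{p}.{q}"] = fam
            used[f"enf:{v}:{p}.{q}"] = 1

    # singleton families for every individual missing a side
    assigned_m = {iid for fam in maternal.values() for iid in fam}
    assigned_p = {iid for fam in paternal.values() for iid in fam}
    for iid in genotypes:
        if iid not in assigned_m:
            maternal[f"single:M:{iid}"] = [iid]
        if iid not in assigned_p:
            paternal[f"single:P:{iid}"] = [iid]

    individuals = tuple(
        Individual(iid, (genotypes[iid],)) for iid in sorted(genotypes)
    )
    pop = Population(individuals, ("L0",))
    partition = make_partition(
        (maternal[k] for k in sorted(maternal)),
        (paternal[k] for k in sorted(paternal)),
    )
    return ReductionOutput(
        instance=instance,
        pop=pop,
        partition=partition,
        literal_allele=dict(y),
        clause_alleles=s,
        z_allele=z,
        selection_families=tuple(frozenset(f) for f in selection),
    )


def encode_certificate(
    output: ReductionOutput, true_vars: frozenset[str]
) -> tuple[tuple[Genotype, ...], ...]:
    """Parent genotypes realizing a one-in-three assignment, per IP family.

    Selection mothers carry the two false alleles of their clause; mapping
    fathers carry (y_a, z) when x_a is true, else (s_p, y_partner);
    enforcement mothers carry (s_p, s_q) when the variable is true, else
    (y_a, z).  Singleton parents copy their only child's genotype, which
    forces nothing.
    """
    inst = output.instance
    y = output.literal_allele
    s = output.clause_alleles
    z = output.z_allele
    problem = build_removal_problem(output.pop, output.partition)
    fam_sets = [frozenset(output.pop.individuals[e].id for e in fam)
                for fam in problem.families]

    def pair(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a <= b else (b, a)

    genos: list[Genotype] = [None] * len(problem.families)
    # selection mothers
    for p, cl in enumerate(inst.clauses):
        true_here = cl & true_vars
        if len(true_here) != 1:
            raise ValueError(f"assignment not one-in-three on clause {sorted(cl)}")
        false_alleles = sorted(y[v] for v in cl - true_here)
        fam = output.selection_families[p]
        genos[fam_sets.index(fam)] = pair(*false_alleles)
    by_id = output.pop.by_id()
    for fi, members in enumerate(fam_sets):
        if genos[fi] is not None:
            continue
        names = sorted(members)
        if len(members) == 1:
            genos[fi] = by_id[names[0]].genotypes[0]
            continue
        if any(n.startswith("enf(") for n in names):
            # enforcement family: variable and clause pair from member names
            enf = next(n for n in names if n.startswith("enf("))
            var = enf[len("enf("):].split(")")[0]
            p_, q_ = (int(t) for t in enf.split(":")[1].split("."))
            genos[fi] = pair(s[p_], s[q_]) if var in true_vars else pair(y[var], z)
        else:
            # mapping family: recover (clause p, variable a, partner b)
            mapper = next(n for n in names if ":map(s" in n and ",z)" not in n)
            p_ = int(mapper.split(":")[0][1:])
            a_allele = int(mapper.split(",")[1].split(")")[0])
            var = next(v for v, al in y.items() if al == a_allele)
            partner = next(
                n for n in names if ":map(" in n and ",z)" in n and ":map(s" not in n
            )
            b_allele = int(partner.split("map(")[1].split(",")[0])
            genos[fi] = pair(y[var], z) if var in true_vars else pair(s[p_], b_allele)
    return tuple(
        tuple([g]) for g in genos
    )


def decode_parent_choice(
    output: ReductionOutput,
    parent_genotypes: Sequence[Sequence[Genotype]],
    problem: RemovalProblem | None = None,
) -> frozenset[str]:
    """Read the one-in-three assignment off the selection mothers.

    The allele a selection mother does not carry is the clause's true
    literal; the result is checked for cross-clause consistency and verified
    against the full population first.
    """
    if problem is None:
        problem = build_removal_problem(output.pop, output.partition)
    violations = verify_assignment(problem, parent_genotypes)
    if violations:
        raise ValueError(f"assignment is not Mendel-valid: {violations[:3]}")
    fam_sets = [
        frozenset(output.pop.individuals[e].id for e in fam)
        for fam in problem.families
    ]
    inv_y = {al: v for v, al in output.literal_allele.items()}
    truth: dict[str, bool] = {}
    for p, cl in enumerate(output.instance.clauses):
        fi = fam_sets.index(output.selection_families[p])
        mother = parent_genotypes[fi][0]
        if mother is None:
            raise ValueError(f"selection family of clause {p} has no genotype")
        carried = set(mother)
        clause_alleles = {output.literal_allele[v] for v in cl}
        true_alleles = clause_alleles - carried
        if len(true_alleles) != 1:
            raise ValueError(
                f"selection mother {mother} of clause {p} does not pick "
                "exactly one true literal"
            )
        true_var = inv_y[true_alleles.pop()]
        for v in cl:
            val = v == true_var
            if truth.setdefault(v, val) != val:
                raise ValueError(f"inconsistent truth value for {v}")
    return frozenset(v for v, b in truth.items() if b)
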