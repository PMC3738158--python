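# Methods

## Data model

A diploid individual is typed at `m` microsatellite loci; a genotype is an
unordered pair of integer repeat counts, and a failed call (allelic dropout)
is a fully missing locus, written `(*,*)` in files.  Partially missing calls
(one allele read) are normalized to full dropout with a warning — the model
has no notion of a half-known locus.  Per-locus allele sets `A_l` are always
the observed ones; alleles are never re-indexed in user-visible output.

## Mendelian compatibility

A group is a feasible *half-sib* family iff at every locus some unordered
allele pair — the candidate shared parent's genotype — covers every typed
member.  The incremental form used by the clustering is the feasible
parent set: a singleton's parent set at locus `(a, b)` is every genotype
over `A_l ∪ {a,b}` containing `a` or `b` (at most `2k − 1`), dropout loci
are unrestricted, and group feasibility is non-emptiness of the
intersection at every locus.  The two formulations are verified equivalent
exhaustively in the tests.

Full-sib feasibility is the 4-allele property (at most four alleles per
locus in the group) plus the 2-allele property, checked by enumerating the
at most 10 × 10 unordered parent-genotype pairs over the observed alleles
per locus and asking whether every member splits into one allele from each
parent.  At four alleles this enumeration is exact and fast, so no
allele-graph machinery is used.

## Similarity

`s_xy` sums, over loci, the multiset intersection of the two genotypes
(homozygote vs identical homozygote counts 2), skipping loci missing in
either individual; no per-locus normalization.  This is the only convention
consistent with the worked value s = 4 for x = [(1,2),(2,2),(1,3)],
y = [(1,1),(2,2),(2,3)].  The matrix costs O(n²m).

Under uniform allele frequencies the exact per-locus expectations are
computed by enumerating equality patterns (set partitions) of the i.i.d.
parental draws combined with the 16 equally likely inheritance choices;
pattern probabilities are falling factorials of k, so the enumeration is
exact rational arithmetic at any k (including k = 10⁶, where the limits
1, ½, 0 for full/half/unrelated are confirmed numerically).  The unrelated
case equals the closed form (4k² − 4k + 2)/k³ exactly for k = 2..50.  The
printed closed forms for the full- and half-sib cases in the source
material are typographically corrupted, so the enumeration is authoritative
and the limits serve as the cross-check.

### Triplet compatibility fractions

The probability that three individuals, each two i.i.d. uniform alleles
over k, form a compatible triplet is computed exactly by weighted
enumeration over unordered genotypes (heterozygote weight 2, homozygote 1),
delegating to the same Mendelian predicates the clustering uses.  This
measure reproduces the reference full-sib fractions to the printed digit
(56.61% at k = 5, 20.94% at k = 10).  For the half-sib property the exact
values are 95.01% (k = 5) and 74.22% (k = 10); for triplets the half-sib
property is provably equivalent to "some two members share an allele", and
no uniform enumeration convention we examined (ordered or unordered,
with or without repetition, heterozygote-only, finite gene pools) yields
the 96.62%/75.46% sometimes quoted, so the exact enumeration stands.

## The SibJoin heuristic

State: 2n clusters (each individual seeds one per parental side), each with
a feasible parent set; a cluster graph with one vertex per live cluster and
one edge per individual connecting its two clusters.  A merge is accepted
iff the intersected parent set is non-empty at every locus, the graph stays
bipartite (checked by 2-coloring; merging an individual's own two clusters
is a self-loop), and every implied full family — members of the merged
cluster grouped by opposite-side cluster — passes the full-sib check.

Schedule: a similarity threshold sweeps s = 2m … 1.  At level s every
cluster pair with single-linkage similarity ≥ s is a candidate; candidates
are attempted in order of descending similarity, full-sibship-forming
merges (pairs with a common graph neighbor) first within a similarity
value, then larger combined size, then smallest member id — deterministic
by construction, so the `seed` parameter is interface-only.  After each
successful merge the level restarts, which retries pairs rejected earlier
(a merge elsewhere can unlock them).  Using ≥ s rather than = s is the one
scheduling choice the description leaves open: single-linkage similarity
never decreases under merges, so this realizes "always join the most
similar compatible pair" with retry, and it is what reproduces the
reference accuracy table.

Output: the bipartite graph is 2-colored per component (root = smallest
cluster id) and the color classes reported as the maternal/paternal
partitions.  The labels are arbitrary; metrics treat them as exchangeable.
In `single` mode the side with the larger mean cluster size is reported
first, for datasets where only one sex's truth is known.

## Minimum-removal integer program

Given families C (maternal + paternal blocks), child→family maps π₀, π₁
and allele-index maps λ₀, λ₁, the 0/1 program minimizes Σ x_i subject to,
for every family j and locus l, Σ_k y_{j,k}^l ≤ 2, and for every typed
(i, l): x_{0,i}^l + ½(y_{π₀(i),λ₀(i)}^l + y_{π₁(i),λ₁(i)}^l) ≥ 1, the
mirrored orientation constraint, x_{0,i}^l + x_{1,i}^l − x_i^l ≤ 1 and
x_i − x_i^l ≥ 0.  Homozygous children make the two orientation constraints
coincide; the duplication is kept for fidelity to the displayed program.
Dropout loci generate no orientation constraints.  K is per-locus.  The
solver is HiGHS through `scipy.optimize.milp` with a 300 s default time
limit; removing everyone is always feasible, so a missing incumbent is a
solver error, not infeasibility.  Correctness is anchored by an exhaustive
oracle (subsets of removals in increasing size; per-locus backtracking over
family genotypes restricted, without loss of generality, to alleles of the
family's kept children) and by the certificate verifier, which applies the
forced-allele rule: a child's allele pair must orient so each parent's
genotype contains the allele attributed to it; an identical parent genotype
forces nothing.

## SAT reduction

Literal x_i ↦ allele y_i = i (1-based); clause p ↦ allele s_p = n + 1 + p;
one shared allele z = n + m + 2.  Per clause, the selection gadget builds a
maternal family of six (two copies of each allele pair), the mapping gadget
six paternal families, and the enforcement gadget one maternal family per
pair of clauses sharing a variable, consuming two dedicated copies of
(s_p, y_i) from each side's mapping family.  The copy count per mapping
family is max(1, k_i − 1), where k_i is the variable's clause count — the
minimum that gives every enforcement family its own copies while keeping
the k_i = 1 mapping families populated (the printed count in the source is
corrupted; the worked two-clause example is matched exactly under this
choice).  Individuals carrying z, and unconsumed copies, get singleton
families on their unassigned side.  Certificates: selection mothers carry
the two false alleles; mapping fathers carry (y_a, z) when x_a is true,
else (s_p, y_partner); enforcement mothers carry (s_p, s_q) when true, else
(y_a, z); singletons copy their child's genotype (forcing nothing).
Decoding reads the true literal of each clause as the allele its selection
mother does not carry.  Soundness and completeness are tested exhaustively
for all monotone instances with ≤ 5 variables and ≤ 3 clauses:
one-in-three satisfiability ⇔ IP objective 0.

## Simulator

n/f mothers and n/f fathers receive two i.i.d. uniform alleles from
{0..k−1} per locus.  Children come from mother–father pairs: each mother
draws one father uniformly with replacement and produces a brood of f full
siblings, each child inheriting one uniformly chosen allele from each
parent per locus.  Maternal families are therefore full-sib blocks of size
f, and half-sib structure arises when two mothers draw the same father —
with the default eight mothers and fathers roughly a third of fathers are
shared.  This pairing design, rather than an independent father per child,
is what the reconstruction accuracy table presumes; under a per-child
father draw the same heuristic scores far worse at every setting, because
broods stop being full-sib blocks and pair similarities alone cannot
attribute each relation to the correct parental side.  Defaults are
k = 6, m = 6, f = 5, n = 40; n is rounded down to a multiple of f with a
warning.  `inject_dropout` masks each (individual, locus) independently.
What the generator does **not** model: non-uniform allele frequencies,
genotyping error other than dropout, mutation, selfing, or age structure —
so green accuracy tests certify behavior under idealized informative loci,
not on field data.

## Metrics

VI uses natural logarithms throughout and is normalized by ln n where
needed; the base cancels in the normalized score.  HSVI takes the minimum
over the two sex pairings and divides by ln n, so it lies in [0, 1]; for
n < 2 it is defined as 0 when the partitions are identical and is an error
otherwise.  Partition distance is n minus the maximum-weight block matching
(via `scipy.optimize.linear_sum_assignment`).  The "false positives" count
reported by `evaluate` is the size of the union, over both sides under the
HSVI-chosen pairing, of individuals outside the matched block
intersections — the minimum set whose removal aligns each side's matched
blocks.

## Problem sizes and numerical notes

The test suite and acceptance script use the study conditions directly
(n ≤ 100, m ≤ 20, k ≤ 20, ten trials per sweep); the heuristic runs in
milliseconds at these sizes and the IPs solve in well under a second.
Exhaustive oracles are capped at 12 individuals (removal IP) and at 5
variables / 3 clauses (reduction).  Accuracy sweeps compare means of ten
seeded trials; trial-to-trial spread of the mean is about 0.005–0.02
normalized VI at these sizes.  All randomness flows through
`numpy.random.default_rng` seeds; the clustering itself is deterministic
given the input order.

## Known limitations

* Agglomerative joins are never undone; an early wrong merge in
  low-information regimes (k = 2 or m = 2) propagates, which is why
  accuracy degrades sharply there.
* The sex labels of the output are arbitrary per connected component of
  the cluster graph; scores are pairing-minimized, but downstream users
  needing absolute sex assignments must supply external information.
* The IP certifies removal counts, not which individuals are *truly*
  misplaced; the minimum removal set need not coincide with the erroneous
  individuals.
* Dropout is handled as "no constraint", so heavy dropout inflates
  apparent compatibility rather than degrading gracefully.
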