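# sibjoin — half-sibling population reconstruction from microsatellite genotypes

Conservation biologists and molecular ecologists routinely genotype a cohort
of same-generation individuals (a brood of fish, a seed array, an insect
clutch) at a handful of microsatellite loci and ask which of them share a
parent.  Full-sibling reconstruction is well served by existing tools;
**half-sibling** reconstruction — recovering a maternal partition M and a
paternal partition P of the cohort when both sexes may be polygamous — is
much harder: even *deciding* whether a proposed pair of partitions admits
Mendelian-consistent parental genotypes is NP-complete.

This package provides, for diploid populations typed at `m` unordered
microsatellite loci with per-locus allele sets `A_l` of size `k`:

* **SibJoin** (`sibjoin.clustering`) — a fast constrained agglomerative
  heuristic.  Starting from 2n singleton clusters (one per individual per
  parental side), it repeatedly merges the most similar pair of clusters
  that keeps (i) every cluster's feasible shared-parent set non-empty at
  every locus (the *half-sibship property*: some allele pair {a_i, a_j}
  covers every member), (ii) the cluster graph bipartite (one parent of
  each sex per individual, while "maternal"/"paternal" labels stay fluid),
  and (iii) every implied full-sib family consistent with the 4-allele and
  2-allele properties.  Similarity is the shared-allele count
  s_xy = Σ_l |g_x(l) ∩ g_y(l)| (multiset intersection; dropout loci count 0),
  with single-linkage cluster similarity sim(C_i, C_j) = max s_xy.
* **Minimum-removal validation** (`sibjoin.validity`) — a 0/1 integer
  program (HiGHS via `scipy.optimize.milp`) computing the minimum number of
  individuals to remove so a candidate partitioning becomes Mendelian-valid,
  with binary variables x_i (remove individual i) and y_{j,k}^l (family j's
  shared parent carries allele k at locus l), O(m·n) constraints, plus a
  polynomial certificate verifier and an exhaustive-search oracle for small
  instances.
* **NP-hardness instance generator** (`sibjoin.satreduce`) — the
  MONOTONE ONE-IN-THREE SAT → half-sib-validity reduction (selection,
  mapping and enforcement gadgets) with certificate encoding/decoding, used
  as a stress test of the IP.
* **Simulator** (`sibjoin.simulate`) — populations with known truth: equal
  numbers of mothers and fathers with uniform alleles, broods of f full
  siblings per mother, fathers drawn with replacement (polygamy), optional
  allelic dropout.
* **Accuracy metrics** (`sibjoin.metrics`) — variation of information
  VI(P,Q) = H(P) + H(Q) − 2 I(P,Q), the sex-agnostic normalized half-sib
  score HSVI = min(½[VI(M,M′)+VI(P,P′)], ½[VI(M,P′)+VI(P,M′)]) / log n,
  and the matching-based partition distance.
* **Analytics** (`sibjoin.analytics`) — exact expectations of the
  shared-allele count for full-sib / half-sib / unrelated pairs (the
  unrelated case has closed form (4k²−4k+2)/k³), the Hoeffding tail bound
  2·exp(−t²m/2) for the mean similarity over m loci, and exact
  triplet-compatibility fractions under the half- and full-sib properties.

## Worked example

```
$ sibjoin simulate --k 6 --m 8 --n 30 --f 5 --seed 1 --out pop.tsv --truth truth.tsv
wrote 30 individuals x 8 loci to pop.tsv
$ sibjoin infer --in pop.tsv --out partition.tsv
4 maternal / 6 paternal clusters
$ sibjoin evaluate --truth truth.tsv --inferred partition.tsv
{
  "false_positives": 0,
  "hsvi": 0.0,
  "partition_distance_maternal": 0,
  "partition_distance_paternal": 0,
  "sexes_swapped": true,
  "vi_maternal": 0.0,
  "vi_paternal": 0.0
}
```

The simulated cohort has six broods of five; two pairs of mothers happened
to draw the same father, so the true paternal partition has four families
and the maternal one six.  SibJoin recovers both exactly: the normalized
half-sib VI (`hsvi`) is 0 and no individual is misplaced
(`false_positives` 0).  `sexes_swapped: true` records that the
reconstruction's arbitrary side labels matched the truth after exchanging
"maternal" and "paternal" — microsatellites carry no information about
which side is which, so all scores are reported under the better pairing.

The analytic summaries behind the similarity measure:

```
$ sibjoin analytics --k 5
E[shared | full siblings]          1.264000
E[shared | half siblings]          0.928000
E[shared | unrelated]              0.656000
P(triplet half-sib compatible)     0.950080
P(triplet full-sib compatible)     0.566080
```

Validating a candidate partitioning (here the simulated truth, which is
Mendelian-valid, hence objective 0):

```
$ sibjoin validate --in pop.tsv --partition truth.tsv --time-limit 60
{ "objective": 0, "removed_ids": [], ... }
```

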