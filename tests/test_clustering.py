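import numpy as np
import pytest

from sibjoin import (
    SimulationConfig,
    audit_partition,
    hsvi,
    inject_dropout,
    run_sibjoin,
    simulate,
)
from sibjoin.clustering import (
    ACCEPT,
    REJECT_EMPTY_PARENT_SET,
    REJECT_NOT_BIPARTITE,
    SibJoinState,
)
from sibjoin.partition import SibPartition
from sibjoin.population import Individual, Population, genotype


def _mean_hsvi(cfg, seeds=range(5)):
    scores = []
    for seed in seeds:
        b = simulate(SimulationConfig(seed=seed, **cfg))
        part = run_sibjoin(b.pop)
        scores.append(
            hsvi(
                list(b.truth.maternal),
                list(b.truth.paternal),
                list(part.maternal),
                list(part.paternal),
            )
        )
    return float(np.mean(scores))


class TestJoinOperation:
    def test_own_clusters_reject_as_self_loop(self, default_bundle):
        state = SibJoinState(default_bundle.pop)
        assert state.try_join(0, 1) == REJECT_NOT_BIPARTITE

    def test_sextet_join_rejected_by_empty_parent_set(self, sextet_population):
        state = SibJoinState(sextet_population)
        # merge the first five individuals' even-side clusters: all accepted
        for j in range(1, 5):
            assert state.try_join(0, 2 * j) == ACCEPT
        assert state.try_join(0, 10) == REJECT_EMPTY_PARENT_SET

    def test_rejection_leaves_state_unchanged(self, sextet_population):
        state = SibJoinState(sextet_population)
        for j in range(1, 5):
            state.try_join(0, 2 * j)
        before = {c: set(cl.members) for c, cl in state.clusters.items()}
        state.try_join(0, 10)
        assert {c: set(cl.members) for c, cl in state.clusters.items()} == before

    def test_joining_dead_cluster_raises(self, default_bundle):
        state = SibJoinState(default_bundle.pop)
        assert state.try_join(0, 2) == ACCEPT
        with pytest.raises(ValueError):
            state.try_join(4, 2)

    def test_cluster_similarity_matches_brute_force(self, default_bundle):
        state = SibJoinState(default_bundle.pop)
        state.run()
        live = sorted(state.clusters)
        S = state.S
        for idx, a in enumerate(live):
            for b in live[idx + 1:]:
                brute = max(
                    (
                        int(S[x, y])
                        for x in state.clusters[a].members
                        for y in state.clusters[b].members
                        if x != y
                    ),
                    default=-1,
                )
                assert state.cluster_similarity(a, b) == brute


class TestRunSibjoin:
    def test_zero_similarity_pair_stays_singletons(self):
        pop = Population(
            (
                Individual("a", ((1, 2),)),
                Individual("b", ((3, 4),)),
            ),
            ("L0",),
        )
        part = run_sibjoin(pop)
        assert len(part.maternal) == 2 and len(part.paternal) == 2

    def test_deterministic_given_seed_and_order(self, default_bundle):
        p1 = run_sibjoin(default_bundle.pop, seed=1)
        p2 = run_sibjoin(default_bundle.pop, seed=1)
        assert p1 == p2

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            run_sibjoin(Population((), ()))

    def test_unknown_mode_raises(self, default_bundle):
        with pytest.raises(ValueError):
            run_sibjoin(default_bundle.pop, mode="nope")

    def test_single_mode_reports_better_resolved_side_first(self, default_bundle):
        part = run_sibjoin(default_bundle.pop, mode="single")
        mean = lambda side: sum(map(len, side)) / len(side)
        assert mean(part.maternal) >= mean(part.paternal)

    def test_high_locus_count_recovers_truth(self):
        """With 20 informative loci the reconstruction is essentially exact."""
        b = simulate(SimulationConfig(k=6, m=20, n=40, f=5, seed=0))
        part = run_sibjoin(b.pop)
        assert (
            hsvi(
                list(b.truth.maternal),
                list(b.truth.paternal),
                list(part.maternal),
                list(part.paternal),
            )
            < 0.01
        )

    def test_monogamous_families_fully_recovered(self):
        """Distinct fathers per mother: full families == maternal families."""
        rng = np.random.default_rng(0)
        for seed in range(5):
            k, m, f, n_fam = 6, 12, 5, 6
            r = np.random.default_rng(seed)
            mothers = r.integers(0, k, size=(n_fam, m, 2))
            fathers = r.integers(0, k, size=(n_fam, m, 2))
            inds = []
            fams = []
            for mi in range(n_fam):
                fam = []
                for c in range(f):
                    picks = r.integers(0, 2, size=(m, 2))
                    gs = tuple(
                        genotype(
                            int(mothers[mi, l, picks[l, 0]]),
                            int(fathers[mi, l, picks[l, 1]]),
                        )
                        for l in range(m)
                    )
                    iid = f"c{mi}.{c}"
                    inds.append(Individual(iid, gs))
                    fam.append(iid)
                fams.append(frozenset(fam))
            pop = Population(tuple(inds), tuple(f"L{l}" for l in range(m)))
            part = run_sibjoin(pop)
            # the implied full families are exactly the broods; one side may
            # additionally pool two broods as plausible half-sibs, which the
            # genotypes alone cannot exclude
            assert set(part.full_families()) == set(fams)

    def test_accuracy_improves_with_loci_and_alleles(self):
        by_m = [_mean_hsvi(dict(k=6, m=m, n=40, f=5)) for m in (2, 6, 20)]
        assert by_m[0] > by_m[1] > by_m[2]
        by_k = [_mean_hsvi(dict(k=k, m=6, n=40, f=5)) for k in (2, 6, 20)]
        assert by_k[0] > by_k[1] > by_k[2]
        assert all(np.isfinite(v) for v in by_m + by_k)


class TestAudit:
    def test_simulated_outputs_pass_audit(self):
        for seed in range(3):
            b = simulate(SimulationConfig(k=5, m=5, n=30, f=5, seed=seed))
            part = run_sibjoin(b.pop)
            assert audit_partition(b.pop, part) == []

    def test_audit_survives_dropout(self):
        b = simulate(SimulationConfig(k=5, m=6, n=30, f=5, seed=4))
        b = inject_dropout(b, rate=0.2, seed=9)
        part = run_sibjoin(b.pop)
        assert audit_partition(b.pop, part) == []

    def test_audit_flags_incompatible_cluster(self, sextet_population):
        ids = [i.id for i in sextet_population.individuals]
        bad = SibPartition(
            (frozenset(ids),), tuple(frozenset({i}) for i in ids)
        )
        problems = audit_partition(sextet_population, bad)
        assert any("not half-sib compatible" in p for p in problems)
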