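import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sibjoin import (
    SimulationConfig,
    full_sib_compatible,
    half_sib_compatible,
    initial_parent_set,
    intersect_parent_sets,
    simulate,
)
from sibjoin.mendel import UNRESTRICTED, fold_parent_sets
from sibjoin.population import Individual


def ind(iid, *genos):
    return Individual(iid, tuple(genos))


SEXTET = [ind(f"i{t}", g) for t, g in enumerate(
    [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]
)]


class TestParentSets:
    def test_heterozygote_candidates(self):
        ps = initial_parent_set(ind("x", (1, 2)), [(1, 2, 3)])
        assert ps.loci[0] == frozenset(
            {(1, 1), (1, 2), (1, 3), (2, 2), (2, 3)}
        )

    def test_homozygote_candidates(self):
        ps = initial_parent_set(ind("x", (2, 2)), [(1, 2)])
        assert ps.loci[0] == frozenset({(1, 2), (2, 2)})

    def test_dropout_is_unrestricted(self):
        ps = initial_parent_set(ind("x", None), [(1, 2, 3)])
        assert ps.loci[0] is UNRESTRICTED
        assert ps.is_feasible()

    def test_singleton_size_is_linear_in_k(self):
        for k in range(2, 12):
            alleles = tuple(range(k))
            ps = initial_parent_set(ind("x", (0, 1)), [alleles])
            assert len(ps.loci[0]) == 2 * k - 1

    def test_unrestricted_is_identity(self):
        p = initial_parent_set(ind("x", (1, 2)), [(1, 2, 3)])
        q = initial_parent_set(ind("y", None), [(1, 2, 3)])
        assert intersect_parent_sets(p, q) == p
        assert intersect_parent_sets(q, p) == p

    def test_disjoint_intersection_is_empty(self):
        p = initial_parent_set(ind("x", (1, 1)), [(1, 2, 3, 4)])
        q = initial_parent_set(ind("y", (2, 2)), [(1, 2, 3, 4)])
        r = initial_parent_set(ind("z", (3, 3)), [(1, 2, 3, 4)])
        assert intersect_parent_sets(intersect_parent_sets(p, q), r).empty_loci() == [0]

    @settings(max_examples=50, derandomize=True)
    @given(
        genos=st.lists(
            st.one_of(
                st.none(), st.tuples(st.integers(0, 3), st.integers(0, 3))
            ),
            min_size=3,
            max_size=3,
        )
    )
    def test_intersection_commutes_and_associates(self, genos):
        alleles = [tuple(range(4))]
        sets = [
            initial_parent_set(ind(f"i{t}", None if g is None else tuple(sorted(g))), alleles)
            for t, g in enumerate(genos)
        ]
        p, q, r = sets
        assert intersect_parent_sets(p, q) == intersect_parent_sets(q, p)
        assert intersect_parent_sets(intersect_parent_sets(p, q), r) == (
            intersect_parent_sets(p, intersect_parent_sets(q, r))
        )


class TestHalfSib:
    def test_sextet_is_incompatible(self):
        assert not half_sib_compatible(SEXTET)

    def test_every_five_subset_is_compatible(self):
        for sub in itertools.combinations(SEXTET, 5):
            assert half_sib_compatible(list(sub))

    def test_any_pair_is_compatible(self):
        for x, y in itertools.combinations(SEXTET, 2):
            assert half_sib_compatible([x, y])

    def test_equals_parent_set_fold_exhaustively(self):
        """Predicate == non-empty parent-set fold, all groups <=4 over k=4."""
        alleles = [tuple(range(4))]
        genos = [(a, b) for a in range(4) for b in range(a, 4)]
        inds = {g: ind(str(g), g) for g in genos}
        for size in (1, 2, 3, 4):
            for combo in itertools.combinations_with_replacement(genos, size):
                group = [
                    ind(f"{t}:{g}", g) for t, g in enumerate(combo)
                ]
                direct = half_sib_compatible(group, alleles)
                folded = fold_parent_sets(group, alleles).is_feasible()
                assert direct == folded, combo

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            half_sib_compatible([])


class TestFullSib:
    def test_two_disjoint_heterozygotes_are_compatible(self):
        assert full_sib_compatible([ind("x", (1, 2)), ind("y", (3, 4))])

    def test_five_alleles_violate_four_allele_property(self):
        group = [ind("x", (1, 2)), ind("y", (3, 4)), ind("z", (5, 6))]
        assert not full_sib_compatible(group)

    def test_two_allele_property_beyond_allele_count(self):
        # four alleles, but no maternal/paternal split explains all three
        group = [ind("x", (1, 1)), ind("y", (2, 2)), ind("z", (3, 4))]
        assert not full_sib_compatible(group)

    def test_simulated_full_families_are_compatible(self):
        bundle = simulate(SimulationConfig(k=6, m=6, n=40, f=5, seed=2))
        by_id = bundle.pop.by_id()
        for fam in bundle.truth.full_families():
            assert full_sib_compatible([by_id[i] for i in fam])

    def test_missing_loci_are_skipped(self):
        group = [ind("x", (1, 2), None), ind("y", (3, 4), (5, 6))]
        assert full_sib_compatible(group)
        assert half_sib_compatible(group)


@settings(max_examples=80, derandomize=True)
@given(
    genos=st.lists(
        st.tuples(st.integers(0, 4), st.integers(0, 4)), min_size=1, max_size=6
    ),
    extra=st.tuples(st.integers(0, 4), st.integers(0, 4)),
)
def test_full_implies_half_and_growth_is_monotone(genos, extra):
    group = [ind(f"i{t}", tuple(sorted(g))) for t, g in enumerate(genos)]
    grown = group + [ind("extra", tuple(sorted(extra)))]
    if full_sib_compatible(group):
        assert half_sib_compatible(group)
    # adding a member can only keep or destroy compatibility, never create it
    if not half_sib_compatible(group):
        assert not half_sib_compatible(grown)
    if not full_sib_compatible(group):
        assert not full_sib_compatible(grown)
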