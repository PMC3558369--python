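"""Group construction, condition auditing and enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmkit.groups import (
    DNA,
    Alphabet,
    GroupAction,
    Permutation,
    build_cyclic,
    build_from_construction,
    build_product,
    check_conditions,
    compose,
    coset_partition,
    enumerate_constructions,
    enumerate_four_cycle_groups,
    isomorphism_key,
    kronecker,
    parse_group_spec,
    reduce_by_isomorphism,
    z2,
)
from osmkit.modelcompat import sgtr_permutation_set

perm_strategy = st.integers(2, 20).flatmap(
    lambda r: st.permutations(range(r)).map(lambda m: Permutation(tuple(m))))


class TestCompose:
    def test_k3st_involutions(self, K3ST):
        for s in K3ST.elements[1:]:
            assert compose(s, s) == K3ST.identity

    def test_z4_generator_squares_to_s2(self, Z4):
        s1 = Z4.element("s'1")
        assert compose(s1, s1) == Z4.element("s'2")

    @given(perm_strategy)
    @settings(max_examples=50, deadline=None)
    def test_identity_is_neutral(self, p):
        e = Permutation.identity(p.size)
        assert compose(p, e) == p == compose(e, p)

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError):
            compose(Permutation.identity(2), Permutation.identity(3))

    @given(perm_strategy, st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_matrix_of_composition_is_matrix_product(self, a, rnd):
        """Under the printed row convention, matrix(a∘b) = matrix(b)·matrix(a)."""
        m = list(range(a.size))
        rnd.shuffle(m)
        b = Permutation(tuple(m))
        assert np.array_equal(compose(a, b).matrix, b.matrix @ a.matrix)

    def test_matrix_product_order_irrelevant_in_abelian_group(self, K3ST, Z4):
        for g in (K3ST, Z4):
            for a in g:
                for b in g:
                    c = compose(a, b)
                    assert np.array_equal(c.matrix, a.matrix @ b.matrix)


class TestKronecker:
    def test_transition_lift_printed_matrix(self):
        """τ1⊗τ0 is the A/G + C/T swap with rows (0010),(0001),(1000),(0100)."""
        t0, t1 = Permutation.identity(2), Permutation((1, 0))
        expected = np.array([[0, 0, 1, 0], [0, 0, 0, 1], [1, 0, 0, 0], [0, 1, 0, 0]])
        assert np.array_equal(kronecker(t1, t0).matrix, expected)

    def test_identity_kron_identity(self):
        t0 = Permutation.identity(2)
        assert kronecker(t0, t0) == Permutation.identity(4)

    def test_three_flips_applied_twice_is_identity(self):
        t1 = Permutation((1, 0))
        triple = kronecker(kronecker(t1, t1), t1)
        assert triple.size == 8
        assert compose(triple, triple) == Permutation.identity(8)

    def test_matrix_is_kronecker_of_matrices(self, K3ST, Z4):
        a, b = K3ST.element("s1"), Z4.element("s'1")
        assert np.array_equal(kronecker(a, b).matrix, np.kron(a.matrix, b.matrix))

    @given(st.permutations(range(2)), st.permutations(range(3)), st.permutations(range(4)))
    @settings(max_examples=30, deadline=None)
    def test_associative_on_flat_indices(self, ma, mb, mc):
        a, b, c = (Permutation(tuple(m)) for m in (ma, mb, mc))
        assert kronecker(a, kronecker(b, c)) == kronecker(kronecker(a, b), c)


class TestBuildCyclic:
    def test_z4_generator_printed_matrix(self, Z4):
        expected = np.array([[0, 0, 1, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 1, 0, 0]])
        assert np.array_equal(Z4.element("s'1").matrix, expected)

    def test_z2_is_identity_and_flip(self):
        g = build_cyclic(2)
        assert g.mapping_set() == z2().mapping_set() == {(0, 1), (1, 0)}

    def test_z5_nonidentity_fixed_point_free(self):
        g = build_cyclic(5)
        assert len(g) == 5
        assert all(not p.fixed_points() for p in g.elements[1:])

    def test_non_full_cycle_generator_rejected(self):
        with pytest.raises(ValueError, match="full cycle"):
            build_cyclic(cycle=Permutation((1, 0, 3, 2)), alphabet=DNA)


class TestBuildProduct:
    def test_z2_squared_is_klein_four(self, K3ST):
        g = build_product([z2(), z2()], alphabet=DNA)
        assert g.mapping_set() == K3ST.mapping_set()

    def test_z4_times_z5_has_twenty_elements(self):
        g = build_product([build_cyclic(4), build_cyclic(5)])
        assert len(g) == 20 and g.alphabet.size == 20
        assert g.condition_report().ok

    def test_single_factor_is_the_factor(self):
        g = build_product([z2()], alphabet=Alphabet("01"))
        assert g.mapping_set() == z2().mapping_set()

    def test_empty_factor_list_rejected(self):
        with pytest.raises(ValueError):
            build_product([])


class TestConditions:
    def test_k3st_passes_all(self, K3ST):
        report = check_conditions(K3ST.elements, DNA)
        assert report.ok and not report.failures()

    def test_sgtr_fails_closure_commutativity_fixed_points(self):
        perms = list(sgtr_permutation_set().values())
        report = check_conditions(perms, DNA)
        assert not report.ok
        for cond in ("C3", "C4", "C5"):
            assert not report[cond].passed
            assert report[cond].witness
        assert report["C1"].passed and report["C7"].passed

    def test_singleton_identity_passes(self):
        report = check_conditions([Permutation.identity(1)], Alphabet("A"))
        assert report.ok

    @pytest.mark.parametrize("r", range(2, 21))
    def test_every_cyclic_group_qualifies(self, r):
        g = build_cyclic(r)
        assert len(g) == r
        assert g.condition_report().ok

    @pytest.mark.parametrize("r", range(2, 21))
    def test_every_product_construction_qualifies(self, r):
        for factors in enumerate_constructions(r):
            g = build_from_construction(factors)
            assert len(g) == r
            assert g.condition_report().ok


class TestTransformer:
    def test_k3st_g_to_a_is_transition(self, K3ST):
        assert K3ST.transformer("G", "A") == K3ST.element("s1")

    def test_z4_g_to_a_is_cube(self, Z4):
        assert Z4.transformer("G", "A") == Z4.element("s'3")

    @pytest.mark.parametrize("r", [2, 4, 5, 6, 20])
    def test_regularity_and_inversion(self, r):
        g = build_cyclic(r)
        letters = g.alphabet.letters
        for x in letters:
            assert g.transformer(x, x).is_identity
            for y in letters:
                p = g.transformer(x, y)
                assert p.apply_letter(g.alphabet, x) == y
                assert p.inverse().apply_letter(g.alphabet, y) == x
                # uniqueness: exactly one element makes the move
                assert sum(q.apply_letter(g.alphabet, x) == y for q in g) == 1


class TestEnumeration:
    def test_six_four_cycles_three_groups(self):
        enum = enumerate_four_cycle_groups(DNA)
        assert enum.count_cycles == 6
        assert enum.distinct_groups == 3
        assert all(v == 2 for v in enum.cycles_per_group.values())

    def test_wrong_alphabet_size_rejected(self):
        with pytest.raises(ValueError):
            enumerate_four_cycle_groups(Alphabet("AB"))

    @pytest.mark.parametrize("r,expected", [
        (20, [(2, 2, 5), (2, 10), (4, 5), (20,)]),
        (4, [(2, 2), (4,)]),
        (2, [(2,)]),
    ])
    def test_constructions(self, r, expected):
        assert enumerate_constructions(r) == expected

    def test_r_below_two_rejected(self):
        with pytest.raises(ValueError):
            enumerate_constructions(1)

    def test_twenty_state_constructions_fall_in_two_isomorphism_classes(self):
        groups = [build_from_construction(f) for f in enumerate_constructions(20)]
        assert len(groups) == 4
        assert len(reduce_by_isomorphism(groups)) == 2
        # Z20 and Z4xZ5 are the cyclic class
        assert isomorphism_key(groups[-1]) == isomorphism_key(groups[2])


class TestCosets:
    def test_z5_in_z2z2z5_gives_four_blocks_of_five(self):
        g = build_from_construction((2, 2, 5))
        # the Z5 subgroup: identity-labelled elements of the last factor
        sub = [p for p in g if all(p.mapping[i] // 5 == i // 5 for i in range(20))]
        blocks = coset_partition(g, sub)
        assert len(blocks) == 4
        assert all(len(b) == 5 for b in blocks)

    def test_trivial_subgroup_gives_singletons(self, K3ST):
        blocks = coset_partition(K3ST, [K3ST.identity])
        assert blocks == [("A",), ("C",), ("G",), ("T",)]

    def test_z2_factor_in_klein_four_pairs_purines_and_pyrimidines(self, K3ST):
        blocks = coset_partition(K3ST, [K3ST.identity, K3ST.element("s1")])
        assert blocks == [("A", "G"), ("C", "T")]

    def test_foreign_subgroup_rejected(self, K3ST, Z4):
        with pytest.raises(ValueError):
            coset_partition(K3ST, [Z4.element("s'1")])


class TestGroupSpec:
    @pytest.mark.parametrize("spec", ["K3ST", "Z2xZ2"])
    def test_klein_four_specs(self, spec, K3ST):
        assert parse_group_spec(spec).mapping_set() == K3ST.mapping_set()

    def test_explicit_cycle_matches_preset(self, Z4):
        g = parse_group_spec("Z4:A>G>T>C>A")
        assert g.mapping_set() == Z4.mapping_set()

    def test_k2st_uses_the_other_generator(self, Z4):
        g = parse_group_spec("K2ST")
        assert g.condition_report().ok
        assert g.mapping_set() != Z4.mapping_set()

    def test_explicit_permutation_list(self, K3ST):
        g = parse_group_spec("e,(A G)(C T),(A C)(G T),(A T)(C G)", alphabet=DNA)
        assert g.mapping_set() == K3ST.mapping_set()

    def test_inadmissible_explicit_list_raises(self):
        with pytest.raises(ValueError):
            parse_group_spec("e,(A C)", alphabet=DNA)

    def test_twenty_state_products(self):
        for spec in ("Z20", "Z2xZ10", "Z4xZ5", "Z2xZ2xZ5"):
            g = parse_group_spec(spec)
            assert len(g) == 20


def test_group_action_rejects_inadmissible_sets():
    perms = list(sgtr_permutation_set().values())
    with pytest.raises(ValueError, match="not an admissible"):
        GroupAction(DNA, perms)
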