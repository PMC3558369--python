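"""Edge-operator lifts, OSM matrix assembly, Cayley graph, random-walk checks."""

import numpy as np
import pytest
import scipy.io

from osmkit.fixtures import random_rooted_tree
from osmkit.groups import kronecker
from osmkit.osm import (
    build_cayley_graph,
    build_osm,
    build_sigma_T,
    cayley_shortest_path,
    char_index,
    index_to_char,
    lift_to_edge,
    min_power_positive,
    stationary_check,
)
from osmkit.phylo import EdgeWeights, normalize_weights, parse_newick


def osm_for(tree, group, uniform=True, lengths=None):
    w = normalize_weights(tree, group.size - 1, uniform=uniform, lengths=lengths)
    return build_osm(tree, group, w)


class TestLift:
    def test_cherry_lift_is_kron_square_and_symmetric(self, fig1_tree, K3ST):
        op = lift_to_edge(fig1_tree, K3ST, "e_12", "s1")
        m = op.matrix(sparse=False)
        s1 = K3ST.element("s1")
        assert m.shape == (16, 16)
        assert np.array_equal(m, np.kron(s1.matrix, s1.matrix))
        assert np.array_equal(m, m.T)

    def test_pendant_lift_is_kron_with_identity(self, fig1_tree, K3ST):
        op = lift_to_edge(fig1_tree, K3ST, "e_1", "s1")
        s0, s1 = K3ST.identity, K3ST.element("s1")
        assert np.array_equal(op.matrix(sparse=False),
                              np.kron(s1.matrix, s0.matrix))

    def test_involution_lift_applied_twice_is_identity(self, fig1_tree, K3ST):
        op = lift_to_edge(fig1_tree, K3ST, "e_2", "s3")
        idx = np.arange(16)
        assert np.array_equal(op.apply_indices(op.apply_indices(idx)), idx)

    def test_identity_lift_rejected(self, fig1_tree, K3ST):
        with pytest.raises(ValueError, match="identity"):
            lift_to_edge(fig1_tree, K3ST, "e_1", "s0")

    def test_lift_matches_positionwise_application(self, fig2_tree, Z4):
        op = lift_to_edge(fig2_tree, Z4, "e_345", "s'2")
        f = "GTAGA"
        expected = op.apply_character(f)
        a = Z4.alphabet
        assert op.apply_indices(np.array([char_index(f, a)]))[0] == char_index(expected, a)

    @pytest.mark.parametrize("seed", range(10))
    def test_internal_lift_equals_product_of_pendant_lifts(self, seed, K3ST, Z4):
        """An internal-edge operator equals the composition of its descendants' pendant lifts."""
        rng = np.random.default_rng(seed)
        group = (K3ST, Z4)[seed % 2]
        t = random_rooted_tree(int(rng.integers(2, 7)), rng)
        idx = np.arange(group.alphabet.size ** t.n_leaves)
        for e in t.internal_edges():
            for s in group.elements[1:]:
                lifted = lift_to_edge(t, group, e, s).apply_indices(idx)
                acc = idx
                for x in t.descendants(e):
                    acc = lift_to_edge(t, group, f"e_{x}", s).apply_indices(acc)
                assert np.array_equal(lifted, acc)


class TestSigmaT:
    def test_cherry_has_nine_operators(self, fig1_tree, K3ST):
        assert len(build_sigma_T(fig1_tree, K3ST)) == 9

    def test_single_leaf_has_three(self, K3ST):
        assert len(build_sigma_T(parse_newick("(1);"), K3ST)) == 3

    def test_five_taxon_has_twenty_seven(self, fig2_tree, K3ST):
        assert len(build_sigma_T(fig2_tree, K3ST)) == 27

    @pytest.mark.parametrize("n", [2, 3])
    def test_generators_reach_the_whole_character_space(self, n, K3ST, Z4):
        newick = "((1,2));" if n == 2 else "((1,(2,3)));"
        t = parse_newick(newick)
        for g in (K3ST, Z4):
            size = g.alphabet.size ** n
            maps = [op.index_map() for op in build_sigma_T(t, g)]
            reached = {0}
            frontier = [0]
            while frontier:
                nxt = []
                for m in maps:
                    for v in frontier:
                        w = int(m[v])
                        if w not in reached:
                            reached.add(w)
                            nxt.append(w)
                frontier = nxt
            assert len(reached) == size


class TestOSMMatrix:
    def test_doubly_stochastic_uniform_weights(self, fig1_tree, K3ST):
        m = osm_for(fig1_tree, K3ST)
        assert m.size == 16
        assert m.is_doubly_stochastic(tol=1e-12)

    def test_powers_stay_doubly_stochastic(self, fig1_tree, K3ST):
        m = osm_for(fig1_tree, K3ST).matrix
        sq = (m @ m).toarray()
        assert np.allclose(sq.sum(axis=0), 1, atol=1e-12)
        assert np.allclose(sq.sum(axis=1), 1, atol=1e-12)

    def test_cherry_transition_entry(self, fig1_tree, K3ST):
        """Only the cherry-edge transition maps AA to GG, so the entry is p·α = 1/9."""
        m = osm_for(fig1_tree, K3ST)
        movers = [op for op in m.operators if op.apply_character("AA") == "GG"]
        assert [op.label for op in movers] == ["e_12:s1"]
        assert m.entry("AA", "GG") == pytest.approx(1 / 9, abs=1e-15)

    def test_unnormalized_weights_rejected(self, fig1_tree, K3ST):
        w = EdgeWeights({e: 1.0 for e in fig1_tree.edges},
                        {e: np.full(3, 1 / 3) for e in fig1_tree.edges})
        with pytest.raises(ValueError):
            build_osm(fig1_tree, K3ST, w)

    def test_involution_group_gives_symmetric_matrix(self, fig1_tree, K3ST, Z4):
        """Every K3ST element is an involution, so its OSM matrix is symmetric for
        any weighting; Z4 pairs s'1 with its inverse s'3, so symmetry survives only
        as long as the two get equal weight."""
        alpha = {e: np.array([0.5, 0.3, 0.2]) for e in fig1_tree.edges}
        wk = normalize_weights(fig1_tree, 3, uniform=True, alpha=alpha)
        mk = build_osm(fig1_tree, K3ST, wk).matrix.toarray()
        assert np.array_equal(mk, mk.T)
        mz = build_osm(fig1_tree, Z4, wk).matrix.toarray()
        assert not np.array_equal(mz, mz.T)
        # uniform type weights give each element the same weight as its inverse
        mz_uniform = osm_for(fig1_tree, Z4).matrix.toarray()
        assert np.array_equal(mz_uniform, mz_uniform.T)

    def test_mtx_and_decomposition_export(self, tmp_path, fig1_tree, K3ST):
        m = osm_for(fig1_tree, K3ST)
        out = tmp_path / "osm.mtx"
        m.to_mtx(str(out))
        back = scipy.io.mmread(str(out)).toarray()
        assert np.allclose(back, m.matrix.toarray())
        tsv = m.decomposition_tsv().strip().splitlines()
        assert tsv[0] == "edge\ttype\tweight"
        assert len(tsv) == 1 + 9
        total = sum(float(line.split("\t")[2]) for line in tsv[1:])
        assert total == pytest.approx(1.0, abs=1e-12)


class TestMinPower:
    def test_zero_iff_equal(self, fig1_tree, K3ST):
        m = osm_for(fig1_tree, K3ST)
        assert min_power_positive(m, "AA", "AA") == 0

    def test_single_generator_move(self, fig1_tree, K3ST):
        m = osm_for(fig1_tree, K3ST)
        assert min_power_positive(m, "AA", "GG") == 1

    def test_five_taxon_example_matches_algorithm(self, fig2_tree, K3ST):
        from osmkit.transform import min_substitutions

        m = osm_for(fig2_tree, K3ST)
        k = min_power_positive(m, "GTAGA", "ACCTC")
        assert k == 2 == min_substitutions(fig2_tree, K3ST, "GTAGA", "ACCTC")

    def test_zero_weights_refused(self, fig1_tree, K3ST):
        lengths = {"e_12": 0.0, "e_1": 1.0, "e_2": 1.0}
        m = osm_for(fig1_tree, K3ST, uniform=False, lengths=lengths)
        with pytest.raises(ValueError, match="positive"):
            min_power_positive(m, "AA", "GG")


class TestCayley:
    def test_zero_distance(self, fig1_tree, K3ST):
        assert cayley_shortest_path(fig1_tree, K3ST, "AA", "AA") == (0, [])

    def test_two_step_move_with_valid_witness(self, fig1_tree, K3ST):
        length, path = cayley_shortest_path(fig1_tree, K3ST, "AA", "GC")
        assert length == len(path) == 2
        # replay the witness path
        ops = {op.label: op for op in build_sigma_T(fig1_tree, K3ST)}
        cur = "AA"
        for label in path:
            cur = ops[label].apply_character(cur)
        assert cur == "GC"

    def test_five_taxon_example_distance(self, fig2_tree, K3ST):
        length, _ = cayley_shortest_path(fig2_tree, K3ST, "GTAGA", "ACCTC")
        assert length == 2

    def test_explicit_graph_degree_bound(self, fig1_tree, K3ST):
        graph = build_cayley_graph(fig1_tree, K3ST)
        assert graph.number_of_nodes() == 16
        bound = len(fig1_tree.edges) * (K3ST.size - 1)
        assert max(d for _, d in graph.degree()) <= bound


class TestStationary:
    def test_uniform_is_fixed_and_attracting(self, fig1_tree, K3ST):
        m = osm_for(fig1_tree, K3ST)
        report = stationary_check(m, steps=200, tol=1e-6, start="AA")
        assert report["uniform_is_fixed"]
        assert report["converged"]
        assert report["power_deviation"] < 1e-6


def test_char_index_roundtrip(K3ST):
    a = K3ST.alphabet
    for i in range(64):
        assert char_index(index_to_char(i, 3, a), a) == i
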