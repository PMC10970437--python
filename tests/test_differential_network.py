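"""Edge weights, adjacency differences, TOM dissimilarity, DCS, permutations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from drgnet import (
    AdjacencyDifference,
    CorrelationPair,
    DissimilarityMatrix,
    PairedDesign,
    Subnetwork,
    adjacency_difference,
    average_dissimilarity,
    build_paired_design,
    dcs_statistic,
    diffcoex_adjacency,
    edge_weight_matrix,
    identify_differential_subnetworks,
    permutation_test,
    tom_dissimilarity,
)
from drgnet.differential_network import EdgeWeightMatrix


def tom_oracle(d):
    """Independent triple-loop topological-overlap dissimilarity."""
    p = d.shape[0]
    t = np.ones((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            num = sum(d[i, k] * d[j, k] for k in range(p) if k not in (i, j)) + d[i, j]
            row_i = sum(d[i, k] for k in range(p) if k != i)
            row_j = sum(d[j, k] for k in range(p) if k != j)
            t[i, j] = 1.0 - num / (min(row_i, row_j) + 1.0 - d[i, j])
    return t


def _rand_adjacency(rng, p, scale=0.4):
    d = rng.uniform(0, scale, size=(p, p))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestPairedDesign:
    def test_single_forced_pair(self):
        d = build_paired_design(["s1"], ["r1"], seed=0)
        assert d.pairs == [("s1", "r1")]

    def test_matching_uses_each_id_once(self):
        sens = [f"s{i}" for i in range(100)]
        res = [f"r{i}" for i in range(100)]
        d = build_paired_design(sens, res, seed=1)
        assert [s for s, _ in d.pairs] == sens
        assert sorted(r for _, r in d.pairs) == sorted(res)

    def test_different_seeds_differ(self):
        sens = [f"s{i}" for i in range(100)]
        res = [f"r{i}" for i in range(100)]
        a = build_paired_design(sens, res, seed=0)
        for seed in (1, 2):  # retry once on the (astronomically unlikely) collision
            if build_paired_design(sens, res, seed=seed).pairs != a.pairs:
                break
        else:
            pytest.fail("distinct seeds produced identical matchings twice")

    def test_unequal_groups_rejected(self):
        with pytest.raises(ValueError):
            build_paired_design(["a"], ["b", "c"])


class TestEdgeWeights:
    def test_direct_formula(self, network_factory):
        M = np.array([[0.0, -1.0], [2.0, 0.0]])
        net = network_factory(M, "c0", ["A", "B"])
        W = edge_weight_matrix(net, ["A", "B"])
        assert W.values[0, 1] == W.values[1, 0] == 1.5

    def test_zero_network(self, network_factory):
        net = network_factory(np.zeros((3, 3)), "c0", list("ABC"))
        assert np.all(edge_weight_matrix(net, list("ABC")).values == 0)

    def test_matches_loop_oracle(self, network_factory):
        rng = np.random.default_rng(0)
        B = rng.standard_normal((10, 10))
        np.fill_diagonal(B, 0)
        genes = [f"G{i}" for i in range(10)]
        W = edge_weight_matrix(network_factory(B.copy(), "c0", genes), genes).values
        for i in range(10):
            for j in range(10):
                expected = 0.0 if i == j else (abs(B[i, j]) + abs(B[j, i])) / 2
                assert W[i, j] == pytest.approx(expected, abs=1e-15)

    def test_unknown_gene_rejected(self, network_factory):
        net = network_factory(np.zeros((2, 2)), "c0", ["A", "B"])
        with pytest.raises(KeyError):
            edge_weight_matrix(net, ["A", "Z"])


def _ewm(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return EdgeWeightMatrix(values, genes)


class TestAdjacencyDifference:
    def test_equal_weights_give_zero(self):
        W = _ewm([[0, 0.5], [0.5, 0]])
        D = adjacency_difference(W, _ewm([[0, 0.5], [0.5, 0]]))
        assert np.all(D.values == 0)

    def test_unit_difference_gamma_one(self):
        D = adjacency_difference(_ewm([[0, 1.0], [1.0, 0]]), _ewm(np.zeros((2, 2))))
        assert D.values[0, 1] == pytest.approx(0.5, abs=1e-15)

    def test_gamma_two_parenthesization(self):
        """gamma applies to the whole half-absolute-difference term."""
        D = adjacency_difference(
            _ewm([[0, 0.8], [0.8, 0]]),
            _ewm([[0, 0.6], [0.6, 0]]),
            gamma=2.0,
            normalize=False,
        )
        assert D.values[0, 1] == pytest.approx(0.0196, abs=1e-12)

    def test_normalized_entries_bounded_by_half(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            A = rng.uniform(0, 7, (6, 6))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            B = rng.uniform(0, 7, (6, 6))
            B = (B + B.T) / 2
            np.fill_diagonal(B, 0)
            D = adjacency_difference(_ewm(A), _ewm(B), normalize=True)
            assert D.values.max() <= 0.5 + 1e-12

    def test_mismatched_dimensions_rejected(self):
        with pytest.raises(ValueError):
            adjacency_difference(_ewm(np.zeros((2, 2))), _ewm(np.zeros((3, 3))))


class TestDiffCoEx:
    def _cp(self, cs, cr):
        return CorrelationPair(np.array(cs), np.array(cr), ["A", "B"])

    def test_equal_correlations_give_zero(self):
        cp = self._cp([[1, 0.4], [0.4, 1]], [[1, 0.4], [0.4, 1]])
        assert np.all(diffcoex_adjacency(cp).values == 0)

    def test_opposite_perfect_correlation(self):
        cp = self._cp([[1, 1.0], [1.0, 1]], [[1, -1.0], [-1.0, 1]])
        assert diffcoex_adjacency(cp).values[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_signed_squares(self):
        cp = self._cp([[1, 0.6], [0.6, 1]], [[1, -0.3], [-0.3, 1]])
        assert diffcoex_adjacency(cp).values[0, 1] == pytest.approx(0.225, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            self._cp([[1, 1.2], [1.2, 1]], [[1, 0], [0, 1]])


class TestTomDissimilarity:
    def test_zero_difference_gives_all_ones(self):
        T = tom_dissimilarity(AdjacencyDifference(np.zeros((4, 4))))
        assert np.all(T.values == 1.0)

    def test_three_gene_hand_example(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        T = tom_dissimilarity(AdjacencyDifference(d))
        assert T.values[0, 1] == pytest.approx(0.5, abs=1e-15)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        d = _rand_adjacency(rng, 20)
        T = tom_dissimilarity(AdjacencyDifference(d))
        np.testing.assert_allclose(T.values, tom_oracle(d), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        p=st.integers(3, 12),
    )
    def test_oracle_equivalence_property(self, seed, p):
        d = _rand_adjacency(np.random.default_rng(seed), p)
        T = tom_dissimilarity(AdjacencyDifference(d))
        np.testing.assert_allclose(T.values, tom_oracle(d), atol=1e-12)
        assert np.allclose(T.values, T.values.T)

    def test_invalid_input_rejected(self):
        bad = np.array([[0, 0.1], [0.2, 0]])
        with pytest.raises(ValueError):
            tom_dissimilarity(AdjacencyDifference(bad))
        with pytest.raises(ValueError):
            tom_dissimilarity(AdjacencyDifference(np.array([[0, -0.1], [-0.1, 0]])))


class TestAverageDissimilarity:
    def test_all_ones(self):
        assert average_dissimilarity(DissimilarityMatrix(np.ones((3, 3)))) == 1.0

    def test_includes_diagonal_by_default(self):
        T = DissimilarityMatrix(np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert average_dissimilarity(T) == pytest.approx(0.8, abs=1e-15)
        assert average_dissimilarity(T, include_diagonal=False) == pytest.approx(0.6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(size=(5, 5))
        v = (v + v.T) / 2
        perm = rng.permutation(5)
        assert average_dissimilarity(DissimilarityMatrix(v)) == pytest.approx(
            average_dissimilarity(DissimilarityMatrix(v[np.ix_(perm, perm)]))
        )


def _noise_networks(rng, ids, genes, factory):
    nets = []
    for c in ids:
        M = rng.standard_normal((len(genes), len(genes)))
        nets.append(factory(M, c, genes))
    return nets


class TestDCS:
    def test_identical_pairs_give_exactly_one(self, network_factory):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(5)]
        sub = Subnetwork(genes, [(genes[i], genes[i + 1]) for i in range(4)], "S1")
        M = rng.standard_normal((5, 5))
        nets = [network_factory(M.copy(), c, genes) for c in ["s1", "s2", "r1", "r2"]]
        design = PairedDesign([("s1", "r1"), ("s2", "r2")])
        assert dcs_statistic(design, nets, sub) == 1.0

    def test_single_pair_equals_average_dissimilarity(self, network_factory):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(4)]
        sub = Subnetwork(genes, [(genes[i], genes[i + 1]) for i in range(3)], "S1")
        nets = _noise_networks(rng, ["s1", "r1"], genes, network_factory)
        W_s = edge_weight_matrix(nets[0], genes)
        W_r = edge_weight_matrix(nets[1], genes)
        D = adjacency_difference(W_s, W_r, normalize=True)
        expected = average_dissimilarity(tom_dissimilarity(D))
        got = dcs_statistic(PairedDesign([("s1", "r1")]), nets, sub)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_pair_order(self, network_factory):
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(4)]
        sub = Subnetwork(genes, [(genes[i], genes[i + 1]) for i in range(3)], "S1")
        ids = [f"s{i}" for i in range(3)] + [f"r{i}" for i in range(3)]
        nets = _noise_networks(rng, ids, genes, network_factory)
        pairs = [("s0", "r0"), ("s1", "r1"), ("s2", "r2")]
        a = dcs_statistic(PairedDesign(pairs), nets, sub)
        b = dcs_statistic(PairedDesign(pairs[::-1]), nets, sub)
        assert a == pytest.approx(b, abs=1e-14)

    def test_missing_network_names_cell_line(self, network_factory):
        genes = ["A", "B"]
        sub = Subnetwork(genes, [("A", "B")], "S1")
        nets = [network_factory(np.zeros((2, 2)), "s1", genes)]
        with pytest.raises(KeyError, match="r1"):
            dcs_statistic(PairedDesign([("s1", "r1")]), nets, sub)

    def test_chain_preserves_symmetry(self, network_factory):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(6)]
        nets = _noise_networks(rng, ["s", "r"], genes, network_factory)
        W_s = edge_weight_matrix(nets[0], genes)
        W_r = edge_weight_matrix(nets[1], genes)
        assert np.allclose(W_s.values, W_s.values.T)
        D = adjacency_difference(W_s, W_r)
        assert np.allclose(D.values, D.values.T)
        T = tom_dissimilarity(D)
        assert np.allclose(T.values, T.values.T)


class TestPermutationTest:
    def test_identical_networks_give_p_one_in_both_modes(self, network_factory):
        genes = ["A", "B", "C"]
        sub = Subnetwork(genes, [("A", "B"), ("B", "C")], "S1")
        M = np.array([[0, 1.0, 0], [0, 0, 2.0], [0, 0, 0.0]])
        ids = ["s1", "s2", "r1", "r2"]
        nets = [network_factory(M.copy(), c, genes) for c in ids]
        for mode in ("small-is-extreme", "literal"):
            r = permutation_test(
                ["s1", "s2"], ["r1", "r2"], nets, sub,
                n_permutations=20, tail_mode=mode, seed=0,
            )
            assert r.p_value == 1.0
            assert r.dcs_observed == 1.0

    def test_p_value_consistent_with_permutation_distribution(self, network_factory):
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(4)]
        sub = Subnetwork(genes, [(genes[i], genes[i + 1]) for i in range(3)], "S1")
        ids = [f"s{i}" for i in range(5)] + [f"r{i}" for i in range(5)]
        nets = _noise_networks(rng, ids, genes, network_factory)
        r_small = permutation_test(
            ids[:5], ids[5:], nets, sub, n_permutations=99, seed=1
        )
        r_lit = permutation_test(
            ids[:5], ids[5:], nets, sub, n_permutations=99, seed=1, tail_mode="literal"
        )
        assert r_small.p_value == np.mean(r_small.dcs_permuted <= r_small.dcs_observed)
        assert r_lit.p_value == np.mean(r_lit.dcs_observed <= r_lit.dcs_permuted)
        # the two tails overlap exactly at ties
        assert r_small.p_value + r_lit.p_value >= 1.0

    def test_zero_permutations_rejected(self, network_factory):
        genes = ["A", "B"]
        sub = Subnetwork(genes, [("A", "B")], "S1")
        nets = [network_factory(np.zeros((2, 2)), c, genes) for c in ["s", "r"]]
        with pytest.raises(ValueError):
            permutation_test(["s"], ["r"], nets, sub, n_permutations=0)


class TestIdentifySubnetworks:
    def test_empty_input_gives_empty_output(self):
        assert identify_differential_subnetworks([], [], [], []) == []

    def test_invariant_to_subnetwork_order(self, network_factory):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(6)]
        ids = [f"s{i}" for i in range(4)] + [f"r{i}" for i in range(4)]
        nets = _noise_networks(rng, ids, genes, network_factory)
        s1 = Subnetwork(genes[:3], [(genes[0], genes[1]), (genes[1], genes[2])], "S1")
        s2 = Subnetwork(genes[3:], [(genes[3], genes[4]), (genes[4], genes[5])], "S2")
        a = identify_differential_subnetworks([s1, s2], nets, ids[:4], ids[4:], n_permutations=49, seed=5)
        b = identify_differential_subnetworks([s2, s1], nets, ids[:4], ids[4:], n_permutations=49, seed=5)
        pa = {r.subnetwork_id: (r.p_value, r.dcs_observed) for r in a}
        pb = {r.subnetwork_id: (r.p_value, r.dcs_observed) for r in b}
        assert pa == pb

    def test_results_sorted_by_p_then_id(self, network_factory):
        rng = np.random.default_rng(10)
        genes = [f"G{i}" for i in range(6)]
        ids = [f"s{i}" for i in range(4)] + [f"r{i}" for i in range(4)]
        nets = _noise_networks(rng, ids, genes, network_factory)
        s1 = Subnetwork(genes[:3], [(genes[0], genes[1]), (genes[1], genes[2])], "S1")
        s2 = Subnetwork(genes[3:], [(genes[3], genes[4]), (genes[4], genes[5])], "S2")
        out = identify_differential_subnetworks([s1, s2], nets, ids[:4], ids[4:], n_permutations=49, seed=5)
        keys = [(r.p_value, r.subnetwork_id) for r in out]
        assert keys == sorted(keys)
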