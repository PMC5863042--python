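import networkx as nx
import numpy as np
import pytest

from corrclust import (
    local_clustering_barrat,
    local_clustering_onnela,
    local_clustering_unweighted,
    local_clustering_zhang,
    positive_weight_network,
    threshold_network,
)
from corrclust.conventional import UnweightedNetwork, WeightedNetwork
from conftest import random_correlation
from oracles import (
    oracle_barrat,
    oracle_density_edges,
    oracle_onnela,
    oracle_unweighted,
    oracle_zhang,
)

WEIGHTED_FNS = {
    "barrat": (local_clustering_barrat, oracle_barrat),
    "onnela": (local_clustering_onnela, oracle_onnela),
    "zhang": (local_clustering_zhang, oracle_zhang),
}


def random_weighted_network(rng, n):
    rho = random_correlation(rng, n)
    return positive_weight_network(rho)


class TestThreshold:
    def test_theta_above_everything_gives_empty_network(self, rng):
        rho = random_correlation(rng, 6)
        net = threshold_network(rho, theta=1.5)
        assert net.adjacency.sum() == 0
        assert (net.degree == 0).all()

    def test_theta_is_inclusive(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.5
        net = threshold_network(rho, theta=0.5)
        assert net.adjacency[0, 1] == 1

    def test_density_tie_break_is_lexicographic(self):
        rho = np.eye(4)
        for i, j, v in [(0, 1, 0.5), (0, 2, 0.5), (0, 3, 0.5), (1, 2, 0.2), (1, 3, 0.1), (2, 3, 0.9)]:
            rho[i, j] = rho[j, i] = v
        # floor(1/3 * 6) = 2 edges: (2,3) at 0.9, then the tie at 0.5 resolves to (0,1)
        net = threshold_network(rho, edge_density=1 / 3)
        assert net.adjacency[2, 3] == 1 and net.adjacency[0, 1] == 1
        assert net.adjacency.sum() == 4

    def test_density_matches_full_sort_oracle(self, rng):
        rho = random_correlation(rng, 6)
        net = threshold_network(rho, edge_density=0.2)
        want = oracle_density_edges(rho.tolist(), 0.2)
        got = {(i, j) for i, j in zip(*np.nonzero(np.triu(net.adjacency)))}
        assert got == want
        assert len(got) == 3

    def test_rules_are_mutually_exclusive_and_density_validated(self, rng):
        rho = random_correlation(rng, 4)
        with pytest.raises(ValueError):
            threshold_network(rho, theta=0.1, edge_density=0.2)
        with pytest.raises(ValueError):
            threshold_network(rho)
        with pytest.raises(ValueError):
            threshold_network(rho, edge_density=1.2)


class TestPositiveWeights:
    def test_all_negative_matrix_gives_zero_network(self):
        rho = np.full((4, 4), -0.3)
        np.fill_diagonal(rho, 1.0)
        net = positive_weight_network(rho)
        assert net.weights.sum() == 0
        assert (net.strength == 0).all()

    def test_negatives_zeroed_positives_kept(self):
        rho = np.array(
            [
                [1.0, 0.5, -0.2, 0.1],
                [0.5, 1.0, 0.3, -0.4],
                [-0.2, 0.3, 1.0, 0.6],
                [0.1, -0.4, 0.6, 1.0],
            ]
        )
        net = positive_weight_network(rho)
        assert net.weights[0, 2] == 0.0 and net.weights[1, 3] == 0.0
        assert net.weights[0, 1] == 0.5 and net.weights[2, 3] == 0.6
        # hand-summed positive row entries
        assert net.strength[0] == pytest.approx(0.5 + 0.1)
        assert net.strength[2] == pytest.approx(0.3 + 0.6)


class TestUnweighted:
    def test_complete_graph_is_fully_clustered(self):
        a = np.ones((4, 4)) - np.eye(4)
        lc = local_clustering_unweighted(UnweightedNetwork(a))
        assert lc.defined.all()
        np.testing.assert_allclose(lc.values, 1.0)

    def test_star_center_zero_leaves_undefined(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 1
        lc = local_clustering_unweighted(UnweightedNetwork(a))
        assert lc.defined[0] and lc.values[0] == 0.0
        assert not lc.defined[1:].any()

    def test_erdos_renyi_matches_triangle_counter_and_networkx(self):
        g = nx.gnp_random_graph(12, 0.4, seed=99)
        a = nx.to_numpy_array(g)
        lc = local_clustering_unweighted(UnweightedNetwork(a))
        want_v, want_d = oracle_unweighted(a.astype(int).tolist())
        np.testing.assert_array_equal(lc.defined, want_d)
        np.testing.assert_allclose(lc.values[want_d], want_v[want_d], atol=1e-12)
        nx_c = nx.clustering(g)
        for i in range(12):
            if lc.defined[i]:
                assert lc.values[i] == pytest.approx(nx_c[i], abs=1e-12)


class TestWeightedVariants:
    @pytest.mark.parametrize("name", list(WEIGHTED_FNS))
    def test_binary_weights_reduce_to_unweighted(self, rng, name):
        fn, _ = WEIGHTED_FNS[name]
        g = nx.gnp_random_graph(10, 0.5, seed=7)
        a = nx.to_numpy_array(g)
        lc_w = fn(WeightedNetwork(a))
        lc_u = local_clustering_unweighted(UnweightedNetwork(a))
        common = lc_w.defined & lc_u.defined
        np.testing.assert_allclose(lc_w.values[common], lc_u.values[common], atol=1e-12)
        np.testing.assert_array_equal(lc_w.defined, lc_u.defined)

    @pytest.mark.parametrize("name", list(WEIGHTED_FNS))
    def test_uniform_weights_equal_unweighted(self, rng, name):
        fn, _ = WEIGHTED_FNS[name]
        g = nx.gnp_random_graph(9, 0.5, seed=13)
        a = nx.to_numpy_array(g)
        lc_w = fn(WeightedNetwork(0.37 * a))
        lc_u = local_clustering_unweighted(UnweightedNetwork(a))
        np.testing.assert_allclose(
            lc_w.values[lc_w.defined], lc_u.values[lc_w.defined], atol=1e-12
        )

    @pytest.mark.parametrize("name", ["onnela", "zhang"])
    def test_scale_invariance(self, rng, name):
        fn, _ = WEIGHTED_FNS[name]
        net = random_weighted_network(rng, 8)
        scaled = WeightedNetwork(10.0 * net.weights)
        np.testing.assert_allclose(fn(net).values, fn(scaled).values, atol=1e-12)

    @pytest.mark.parametrize("name", list(WEIGHTED_FNS))
    def test_matches_triple_loop_oracle(self, rng, name):
        fn, oracle = WEIGHTED_FNS[name]
        for n in (5, 7):
            net = random_weighted_network(rng, n)
            lc = fn(net)
            want_v, want_d = oracle(net.weights.tolist())
            np.testing.assert_array_equal(lc.defined, want_d)
            np.testing.assert_allclose(lc.values[want_d], want_v[want_d], atol=1e-10)

    def test_onnela_matches_networkx_weighted_clustering(self, rng):
        net = random_weighted_network(rng, 8)
        g = nx.from_numpy_array(net.weights)
        nx_c = nx.clustering(g, weight="weight")
        lc = local_clustering_onnela(net)
        for i in range(8):
            if lc.defined[i]:
                assert lc.values[i] == pytest.approx(nx_c[i], abs=1e-10)

    def test_barrat_k3_hand_evaluation(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.4
        w[1, 2] = w[2, 1] = 0.6
        lc = local_clustering_barrat(WeightedNetwork(w))
        # each node of a triangle has k=2, and the ordered-pair sum equals its
        # strength, so every local value is exactly 1
        np.testing.assert_allclose(lc.values, 1.0, atol=1e-12)

    def test_all_coefficients_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            n = int(rng.integers(4, 10))
            if rng.random() < 0.5:
                net = random_weighted_network(rng, n)
            else:
                w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.5), k=1)
                net = WeightedNetwork(w + w.T)
            for fn, _ in WEIGHTED_FNS.values():
                lc = fn(net)
                vals = lc.values[lc.defined]
                assert (vals >= -1e-12).all() and (vals <= 1.0 + 1e-9).all()

    def test_edgeless_network_fully_undefined(self):
        net = WeightedNetwork(np.zeros((5, 5)))
        for fn, _ in WEIGHTED_FNS.values():
            assert not fn(net).defined.any()
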