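"""Weighted network metrics against brute-force oracles and invariants."""

import numpy as np
import pytest

from connrep import (
    characteristic_path_length,
    clustering_coefficient,
    compute_metrics,
    global_efficiency,
    local_efficiency,
    shortest_path_lengths,
)

import oracles
from conftest import random_weight_matrix


def complete_graph(n, w=1.0):
    W = np.full((n, n), w)
    np.fill_diagonal(W, 0.0)
    return W


def star_graph(n, w=1.0):
    W = np.zeros((n, n))
    W[0, 1:] = w
    W[1:, 0] = w
    return W


class TestShortestPaths:
    def test_single_edge_inverse_weight(self):
        W = np.array([[0.0, 0.5], [0.5, 0.0]])
        d = shortest_path_lengths(W)
        assert d[0, 1] == pytest.approx(2.0)

    def test_two_hop_path(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        d = shortest_path_lengths(W)
        assert d[0, 2] == pytest.approx(2.0)

    def test_negative_weights_rejected(self):
        W = np.array([[0.0, -0.1], [-0.1, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            shortest_path_lengths(W)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_floyd_warshall(self, seed):
        rng = np.random.default_rng(seed)
        W = random_weight_matrix(rng, 6, density=0.5)
        assert np.allclose(
            shortest_path_lengths(W), oracles.floyd_warshall(W), equal_nan=True
        )


class TestTrivialGraphs:
    def test_complete_unit_graph(self):
        W = complete_graph(5)
        assert global_efficiency(W) == pytest.approx(1.0)
        L, n_pairs = characteristic_path_length(W)
        assert L == pytest.approx(1.0)
        assert n_pairs == 20
        assert clustering_coefficient(W) == pytest.approx(1.0)
        assert local_efficiency(W) == pytest.approx(1.0)

    def test_two_nodes(self):
        W = np.array([[0.0, 0.3], [0.3, 0.0]])
        assert global_efficiency(W) == pytest.approx(0.3)

    def test_empty_graph(self):
        W = np.zeros((4, 4))
        assert global_efficiency(W) == 0.0
        L, n_pairs = characteristic_path_length(W)
        assert np.isnan(L) and n_pairs == 0

    def test_star_graph_has_no_triangles(self):
        W = star_graph(6)
        assert clustering_coefficient(W) == 0.0
        assert local_efficiency(W) == 0.0

    def test_two_disconnected_dyads_exclude_infinite_pairs(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.5
        L, n_pairs = characteristic_path_length(W)
        assert L == pytest.approx(2.0)
        assert n_pairs == 4


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 9))
        W = random_weight_matrix(rng, n, density=float(rng.uniform(0.3, 0.9)))
        assert global_efficiency(W) == pytest.approx(
            oracles.global_efficiency(W), rel=1e-10, abs=1e-12
        )
        L, n_pairs = characteristic_path_length(W)
        L_o, n_pairs_o = oracles.characteristic_path_length(W)
        assert n_pairs == n_pairs_o
        if n_pairs:
            assert L == pytest.approx(L_o, rel=1e-10)
        assert clustering_coefficient(W) == pytest.approx(
            oracles.clustering_coefficient(W), rel=1e-10, abs=1e-12
        )
        assert local_efficiency(W) == pytest.approx(
            oracles.local_efficiency(W), rel=1e-10, abs=1e-12
        )


class TestInvariants:
    @pytest.mark.parametrize("c", [0.1, 1.0, 43.2])
    def test_scale_covariance(self, c):
        rng = np.random.default_rng(5)
        W = random_weight_matrix(rng, 10, density=0.5)
        assert global_efficiency(c * W) == pytest.approx(
            c * global_efficiency(W), rel=1e-9
        )
        assert clustering_coefficient(c * W) == pytest.approx(
            c * clustering_coefficient(W), rel=1e-9
        )
        assert local_efficiency(c * W) == pytest.approx(
            c * local_efficiency(W), rel=1e-9
        )
        L, _ = characteristic_path_length(W)
        L_c, _ = characteristic_path_length(c * W)
        assert L_c == pytest.approx(L / c, rel=1e-9)

    def test_binary_limit_matches_networkx(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(11)
        for _ in range(5):
            A = (random_weight_matrix(rng, 8, density=0.45) > 0).astype(float)
            G = nx.from_numpy_array(A)
            assert global_efficiency(A) == pytest.approx(
                nx.global_efficiency(G), rel=1e-10
            )
            if nx.is_connected(G) and G.number_of_edges() > 0:
                L, _ = characteristic_path_length(A)
                assert L == pytest.approx(
                    nx.average_shortest_path_length(G), rel=1e-10
                )
            assert clustering_coefficient(A) == pytest.approx(
                nx.average_clustering(G), rel=1e-10
            )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(21)
        W = random_weight_matrix(rng, 9, density=0.5)
        perm = rng.permutation(9)
        Wp = W[np.ix_(perm, perm)]
        rec, rec_p = compute_metrics(W), compute_metrics(Wp)
        for attr in ("E_glob", "E_loc", "C_w", "L_w"):
            assert getattr(rec, attr) == pytest.approx(getattr(rec_p, attr), rel=1e-10)
        assert rec.n_connected_pairs == rec_p.n_connected_pairs

    def test_bounds_on_probability_weights(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            W = random_weight_matrix(rng, 10, density=0.6)
            assert global_efficiency(W) <= 1.0 + 1e-12
            assert clustering_coefficient(W) <= 1.0 + 1e-12
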