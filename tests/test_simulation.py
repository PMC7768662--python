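import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import skew

from cozine import (
    HurdleParameters,
    SimulationScenario,
    gibbs_sample,
    joint_log_density_unnormalized,
    make_topology,
    sample_parameters,
    simulate_dataset,
    to_counts_and_composition,
    truth_adjacency,
)


class TestTopology:
    def test_chain_structure(self):
        A = make_topology(5, "ar1")
        expected = {(0, 1), (1, 2), (2, 3), (3, 4)}
        edges = {(i, j) for i, j in zip(*np.nonzero(np.triu(A)))}
        assert edges == expected
        assert list(A.sum(axis=0)) == [1, 2, 2, 2, 1]

    def test_scale_free_is_tree(self):
        A = make_topology(10, "ba1", seed=3)
        assert A.sum() // 2 == 9  # p-1 edges
        # connected: BFS reaches everyone
        import networkx as nx

        g = nx.from_numpy_array(A)
        assert nx.is_connected(g) and nx.is_tree(g)

    def test_scale_free_has_hubs(self):
        A = make_topology(200, "ba1", seed=0)
        assert A.sum(axis=0).max() > 2

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="topology"):
            make_topology(5, "erdos")


class TestSampleParameters:
    @pytest.mark.parametrize("setting,g_off,h_off,k_off", [
        ("g_minimal", True, False, False),
        ("k_minimal", False, False, True),
        ("g_k", True, False, True),
        ("h_k", False, True, True),
        ("g_h_k", True, True, True),
    ])
    def test_support_placement(self, setting, g_off, h_off, k_off):
        A = make_topology(8, "ar1")
        params = sample_parameters(A, setting, seed=1)

        def has_offdiag(M):
            M = M.copy()
            np.fill_diagonal(M, 0)
            return np.any(M != 0)

        assert has_offdiag(params.G) == g_off
        assert has_offdiag(params.H) == h_off
        assert has_offdiag(params.K) == k_off

    def test_offdiagonal_magnitudes_below_point_one(self):
        A = make_topology(20, "ba1", seed=2)
        params = sample_parameters(A, "g_h_k", seed=2)
        for M in (params.G, params.H, params.K):
            off = M - np.diag(np.diag(M))
            assert np.all(np.abs(off) < 0.1)

    def test_diagonal_rule_and_positive_definiteness(self):
        A = make_topology(12, "ar1")
        params = sample_parameters(A, "g_h_k", seed=5)
        K = params.K
        off = K - np.diag(np.diag(K))
        np.testing.assert_allclose(np.diag(K), np.abs(off).sum(axis=0) + 0.1, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(K) > 0)

    def test_k_support_restricted_to_second_half(self):
        A = make_topology(10, "ar1")
        params = sample_parameters(A, "g_k", seed=0)
        K = params.K.copy()
        np.fill_diagonal(K, 0)
        assert np.all(K[:5, :] == 0) and np.all(K[:, :5] == 0)
        assert np.any(K[5:, 5:] != 0)

    def test_truth_adjacency_matches_edge_rule(self):
        for setting in ("g_minimal", "k_minimal", "g_k", "h_k", "g_h_k"):
            A = make_topology(8, "ar1")
            params = sample_parameters(A, setting, seed=3)
            np.testing.assert_array_equal(truth_adjacency(params), A)


def exact_presence_pmf(params: HurdleParameters):
    """Oracle joint pmf of the presence configurations by enumeration plus
    Gaussian integration of the continuous part (small p only)."""
    p = params.p
    weights = {}
    for v in itertools.product([0, 1], repeat=p):
        v_arr = np.array(v, dtype=float)
        idx = [i for i in range(p) if v[i] == 1]
        if not idx:
            weights[v] = 1.0  # exp(0)
            continue
        # integrate exp{v'Gv + v'Hy - y'Ky/2} over the present coordinates:
        # Gaussian integral with precision K_sub and linear term (H'v)_sub
        K_sub = params.K[np.ix_(idx, idx)]
        eta = (params.H.T @ v_arr)[idx]
        quad_term = v_arr @ params.G @ v_arr
        log_w = (
            quad_term
            + 0.5 * eta @ np.linalg.solve(K_sub, eta)
            + 0.5 * len(idx) * math.log(2 * math.pi)
            - 0.5 * math.log(np.linalg.det(K_sub))
        )
        weights[v] = math.exp(log_w)
    total = sum(weights.values())
    return {v: w / total for v, w in weights.items()}


class TestGibbs:
    def test_independent_coordinates_match_closed_form(self):
        # diagonal matrices: each coordinate is an independent hurdle
        params = HurdleParameters(
            G=np.diag([0.4, -0.6]), H=np.diag([0.5, 0.2]), K=np.diag([1.5, 0.8])
        )
        n = 20000
        Z, V = gibbs_sample(params, n, burnin=200, thin=2, seed=9)
        from cozine import NodeConditional, presence_probability

        for j in range(2):
            expect = presence_probability(
                NodeConditional(params.G[j, j], params.H[j, j], params.K[j, j])
            )
            freq = V[:, j].mean()
            se = math.sqrt(expect * (1 - expect) / n)
            assert abs(freq - expect) < 3 * se

    def test_p2_joint_pmf_matches_enumeration_oracle(self, p2_params):
        pmf = exact_presence_pmf(p2_params)
        n = 20000
        Z, V = gibbs_sample(p2_params, n, burnin=500, thin=5, seed=4)
        emp = {}
        for v in itertools.product([0, 1], repeat=2):
            emp[v] = np.mean((V[:, 0] == v[0]) & (V[:, 1] == v[1]))
        tv = 0.5 * sum(abs(emp[v] - pmf[v]) for v in pmf)
        assert tv < 0.02

    def test_support_consistency_and_determinism(self, p2_params):
        Z1, V1 = gibbs_sample(p2_params, 100, burnin=50, thin=2, seed=7)
        Z2, V2 = gibbs_sample(p2_params, 100, burnin=50, thin=2, seed=7)
        np.testing.assert_array_equal(Z1, Z2)
        np.testing.assert_array_equal(V1, V2)
        assert np.all((Z1 == 0) == (V1 == 0))

    def test_non_pd_k_rejected(self):
        bad = HurdleParameters(
            G=np.zeros((2, 2)),
            H=np.zeros((2, 2)),
            K=np.array([[1.0, 2.0], [2.0, 1.0]]),
        )
        with pytest.raises(ValueError, match="positive definite"):
            gibbs_sample(bad, 10)


class TestToCountsAndComposition:
    def test_rule_application(self):
        Z = np.array([[0.2, 0.0, -0.1]])
        V = np.array([[1, 0, 1]])
        W, X = to_counts_and_composition(Z, V)
        denom = math.exp(0.2) + math.exp(-0.1)
        np.testing.assert_allclose(W, [[math.exp(0.2), 0.0, math.exp(-0.1)]])
        np.testing.assert_allclose(X, [[math.exp(0.2) / denom, 0.0, math.exp(-0.1) / denom]])

    def test_rows_sum_to_one_and_zero_pattern(self):
        rng = np.random.default_rng(0)
        V = (rng.random((20, 6)) < 0.7).astype(int)
        V[:, 0] = 1
        Z = rng.normal(0, 1, (20, 6)) * V
        _, X = to_counts_and_composition(Z, V)
        np.testing.assert_allclose(X.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(X == 0, V == 0)

    def test_all_absent_row_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            to_counts_and_composition(np.zeros((1, 3)), np.zeros((1, 3), dtype=int))


class TestSimulateDataset:
    def test_default_dimensions(self):
        table, truth = simulate_dataset(
            SimulationScenario(burnin=50, thin=2)  # cheap chain, default p/n
        )
        assert table.shape == (200, 60)

    def test_g_minimal_truth_is_chain(self):
        sc = SimulationScenario(topology="ar1", setting="g_minimal", p=8, n=30, burnin=50, thin=2)
        table, truth = simulate_dataset(sc)
        np.testing.assert_array_equal(truth.adjacency, make_topology(8, "ar1"))
        # H and K exactly diagonal in the g-minimal setting
        assert np.all(truth.params.H == np.diag(np.diag(truth.params.H)))
        assert np.all(truth.params.K == np.diag(np.diag(truth.params.K)))

    def test_nonzero_values_are_right_skewed(self):
        table, _ = simulate_dataset(SimulationScenario(p=30, n=100, seed=2, burnin=100, thin=2))
        nz = table.values[table.values > 0]
        assert skew(nz) > 0

    def test_seed_separation_same_truth_different_data(self):
        sc1 = SimulationScenario(p=10, n=40, seed=5, sampling_seed=1, burnin=50, thin=2)
        sc2 = SimulationScenario(p=10, n=40, seed=5, sampling_seed=2, burnin=50, thin=2)
        t1, truth1 = simulate_dataset(sc1)
        t2, truth2 = simulate_dataset(sc2)
        np.testing.assert_array_equal(truth1.adjacency, truth2.adjacency)
        np.testing.assert_array_equal(truth1.params.G, truth2.params.G)
        assert not np.array_equal(t1.values, t2.values)
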