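import numpy as np
import pytest

from cozine import (
    FitConfig,
    aggregate_network,
    fit_network,
    fit_node,
    group_penalty,
    lambda_max,
    select_model,
    simulate_dataset,
    SimulationScenario,
)
from cozine.simulation import gibbs_sample, make_topology, sample_parameters, truth_adjacency
from cozine.transforms import prepare_yv


def _sim_yv(p=6, n=300, seed=0, setting="g_h_k"):
    table, truth = simulate_dataset(
        SimulationScenario(p=p, n=n, seed=seed, setting=setting, burnin=200, thin=2)
    )
    Y, V = prepare_yv(table)
    return Y, V, truth


class TestGroupPenalty:
    def test_euclidean_norm(self):
        assert group_penalty(np.array([[3.0, 0.0, 4.0, 0.0]]), 1.0) == 5.0

    def test_zero_groups_and_zero_lambda(self):
        assert group_penalty(np.zeros((4, 4)), 2.0) == 0.0
        assert group_penalty(np.ones((4, 4)), 0.0) == 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            group_penalty(np.ones((1, 4)), -0.1)


class TestLambdaMax:
    def test_fit_at_lambda_max_is_empty(self):
        Y, V, _ = _sim_yv(seed=1)
        for i in range(Y.shape[1]):
            lmax = lambda_max(i, Y, V)
            fit = fit_node(i, Y, V, lambda_path=np.array([1.01 * lmax, lmax]))
            assert fit.n_active(0) == 0
            assert fit.n_active(1) == 0

    def test_independent_node_has_small_lambda_max(self):
        rng = np.random.default_rng(0)
        n, p = 4000, 4
        # node 0 independent of the rest by construction
        V = (rng.random((n, p)) < 0.6).astype(int)
        Y = rng.normal(0, 1, (n, p)) * V
        V[:, 0] = (rng.random(n) < 0.5).astype(int)
        Y[:, 0] = rng.normal(0, 1, n) * V[:, 0]
        assert lambda_max(0, Y, V) < 0.1


class TestFitNode:
    def test_block_sparsity_groups_all_or_nothing(self):
        Y, V, _ = _sim_yv(seed=2)
        fit = fit_node(0, Y, V)
        norms = np.linalg.norm(fit.coef, axis=2)
        for l in range(fit.lambda_path.size):
            for pos in range(fit.coef.shape[1]):
                if norms[l, pos] == 0:
                    assert np.all(fit.coef[l, pos] == 0)

    def test_loglik_nondecreasing_as_lambda_decreases(self):
        Y, V, _ = _sim_yv(seed=3)
        fit = fit_node(1, Y, V)
        ok = fit.converged & ~fit.saturated
        ll = fit.loglik[ok]
        assert np.all(np.diff(ll) >= -1e-4 * np.maximum(1.0, np.abs(ll[:-1])))

    def test_deterministic_given_data(self):
        Y, V, _ = _sim_yv(seed=4)
        f1 = fit_node(2, Y, V)
        f2 = fit_node(2, Y, V)
        np.testing.assert_array_equal(f1.coef, f2.coef)
        np.testing.assert_array_equal(f1.intercepts, f2.intercepts)

    def test_kappa_positive_along_path(self):
        Y, V, _ = _sim_yv(seed=5)
        fit = fit_node(0, Y, V)
        assert np.all(np.exp(fit.intercepts[:, 2]) > 0)

    def test_all_present_column_freezes_binary_part(self):
        Y, V, _ = _sim_yv(seed=6)
        V = V.copy()
        Y = Y.copy()
        V[:, 0] = 1
        Y[V == 0] = 0
        rng = np.random.default_rng(0)
        Y[:, 0] = np.where(Y[:, 0] == 0, rng.normal(0, 1, Y.shape[0]), Y[:, 0])
        fit = fit_node(0, Y, V)
        # the g and h_i. components of every group stay frozen at zero
        assert np.all(fit.coef[:, :, 0] == 0)
        assert np.all(fit.coef[:, :, 1] == 0)


class TestSelectModel:
    def test_single_lambda_path_returned(self):
        Y, V, _ = _sim_yv(seed=7)
        lmax = lambda_max(0, Y, V)
        fit = fit_node(0, Y, V, lambda_path=np.array([0.5 * lmax]))
        assert select_model(fit) == 0

    def test_null_data_selects_sparse_neighborhood(self):
        """Independent taxa: BIC should keep the neighborhood (near-)empty."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, p = 500, 10
            V = (rng.random((n, p)) < 0.7).astype(int)
            V[:, 0] = np.maximum(V[:, 0], (V.sum(axis=1) == 0))
            Y = rng.normal(0, 1, (n, p)) * V
            fit = fit_node(0, Y, V)
            if fit.n_active(select_model(fit)) == 0:
                hits += 1
        assert hits >= 9


class TestAggregateNetwork:
    def test_zero_groups_give_no_edge_and_or_rule(self):
        from cozine.estimation import NeighborhoodFit

        def make_fit(node, coef_row):
            others = np.array([j for j in range(3) if j != node])
            coef = np.zeros((1, 2, 4))
            coef[0] = coef_row
            return NeighborhoodFit(
                node=node,
                others=others,
                lambda_path=np.array([0.1]),
                coef=coef,
                intercepts=np.zeros((1, 3)),
                loglik=np.zeros(1),
                objective=np.zeros(1),
                n_iter=np.ones(1, dtype=int),
                converged=np.ones(1, dtype=bool),
                saturated=np.zeros(1, dtype=bool),
                n_samples=10,
            )

        # node 0's regression: h_ij component for neighbor 1 only
        f0 = make_fit(0, [[0.0, 0.3, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]])
        f1 = make_fit(1, [[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]])
        f2 = make_fit(2, [[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]])
        net = aggregate_network([f0, f1, f2], [0, 0, 0], ("a", "b", "c"))
        assert net.edge_set() == {(0, 1)}
        edge = net.edges[0]
        assert edge.components == {"g": False, "h_ij": True, "h_ji": False, "k": False}
        assert edge.weight == pytest.approx(0.3)

    def test_missing_fit_rejected(self):
        with pytest.raises(ValueError):
            aggregate_network([], [], ("a", "b"))


class TestFitNetwork:
    def test_huge_lambda_gives_empty_network(self):
        table, _ = simulate_dataset(SimulationScenario(p=6, n=80, seed=0, burnin=100, thin=2))
        cfg = FitConfig(n_lambda=2, lambda_min_ratio=0.99, select="fixed", fixed_lambda_index=0)
        res = fit_network(table, cfg)
        assert res.network.n_edges == 0

    def test_node_order_invariance(self):
        table, _ = simulate_dataset(SimulationScenario(p=6, n=150, seed=9, burnin=100, thin=2))
        res = fit_network(table, FitConfig(n_lambda=20))
        perm = np.array([3, 1, 5, 0, 2, 4])
        table_p = table.select_taxa(perm)
        res_p = fit_network(table_p, FitConfig(n_lambda=20))
        edges = {tuple(sorted((table.taxon_ids[e.i], table.taxon_ids[e.j]))) for e in res.network.edges}
        edges_p = {tuple(sorted((table_p.taxon_ids[e.i], table_p.taxon_ids[e.j]))) for e in res_p.network.edges}
        assert edges == edges_p

    def test_parallel_fits_match_sequential(self):
        table, _ = simulate_dataset(SimulationScenario(p=5, n=100, seed=10, burnin=100, thin=2))
        r1 = fit_network(table, FitConfig(n_lambda=15, n_jobs=1))
        r2 = fit_network(table, FitConfig(n_lambda=15, n_jobs=2))
        assert r1.network.edge_set() == r2.network.edge_set()
        for f1, f2 in zip(r1.fits, r2.fits):
            np.testing.assert_array_equal(f1.coef, f2.coef)

    def test_diagonal_h_k_data_cozine_agrees_with_ising(self):
        """When only presence structure exists, the two modes should find
        mostly the same edges (on >= 90% of node pairs)."""
        # presence-balanced Ising data on the latent scale, fit directly;
        # the negative field keeps presence near 1/2 (maximal binary
        # information) and the thinning decorrelates the chain
        p, n = 6, 4000
        A = make_topology(p, "ar1")
        G = A * 0.6
        np.fill_diagonal(G, -1.6)
        from cozine import HurdleParameters

        params = HurdleParameters(G=G, H=np.diag(np.full(p, 0.2)), K=np.diag(np.full(p, 1.0)))
        Z, V = gibbs_sample(params, n, burnin=300, thin=10, seed=3)
        keep = V.sum(axis=1) > 0
        Z, V = Z[keep], V[keep]
        from cozine.estimation import fit_node as fn

        def edges_of(mode):
            cfg = FitConfig(mode=mode)
            fits = [fn(i, Z, V, config=cfg) for i in range(p)]
            sel = [select_model(f) for f in fits]
            return aggregate_network(fits, sel, tuple(map(str, range(p)))).adjacency()

        a_coz = edges_of("cozine")
        a_isi = edges_of("ising")
        agree = np.mean(a_coz[np.triu_indices(p, 1)] == a_isi[np.triu_indices(p, 1)])
        assert agree >= 0.9
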