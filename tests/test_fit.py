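import numpy as np
import pytest

from multide import (
    CountMatrix,
    SimConfig,
    estimate_eta,
    fit,
    moment_effects,
    normalize,
    refine_u,
    simulate_rank1,
    wls_rank1,
)
from multide.errors import DegenerateInteractionError, ZeroMeanError
from multide.fit import rank1_svd_oracle
from multide.normalize import SizeFactors, normalize_counts


def _nc(counts, conditions):
    counts = np.asarray(counts)
    cm = CountMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        conditions=conditions,
    )
    return normalize_counts(cm, SizeFactors(np.ones(cm.N), "median", cm.sample_ids))


def _random_gamma(rng, D, G, n_d):
    """Random interaction matrix satisfying both centering constraints."""
    eta = rng.normal(0, 1, (D, G))
    return moment_effects(eta, n_d)[3]


class TestEstimateEta:
    def test_log_of_cell_mean(self):
        eta, mu_dg = estimate_eta(_nc([[2, 4]], [1, 1]))
        assert mu_dg[0, 0] == pytest.approx(3.0)
        assert eta[0, 0] == pytest.approx(np.log(3.0))

    def test_constant_counts(self):
        eta, _ = estimate_eta(_nc([[7, 7, 7, 7]], [1, 1, 2, 2]))
        np.testing.assert_allclose(eta, np.log(7.0))

    def test_zero_mean_cell_raises(self):
        with pytest.raises(ZeroMeanError):
            estimate_eta(_nc([[0, 0]], [1, 1]))


class TestMomentEffects:
    def test_additive_grid(self):
        mu, a, b, g = moment_effects([[1.0, 2.0], [3.0, 4.0]], [1, 1])
        assert mu == pytest.approx(2.5)
        np.testing.assert_allclose(a, [-1.0, 1.0])
        np.testing.assert_allclose(b, [-0.5, 0.5])
        np.testing.assert_allclose(g, 0.0, atol=1e-15)

    def test_pure_interaction(self):
        mu, a, b, g = moment_effects([[0.0, 2.0], [2.0, 0.0]], [1, 1])
        assert mu == pytest.approx(1.0)
        np.testing.assert_allclose(a, 0.0, atol=1e-15)
        np.testing.assert_allclose(b, 0.0, atol=1e-15)
        np.testing.assert_allclose(g, [[-1.0, 1.0], [1.0, -1.0]])

    def test_weighted_by_sample_sizes(self):
        mu, a, b, g = moment_effects([[0.0, 0.0], [4.0, 4.0]], [1, 3])
        assert mu == pytest.approx(3.0)
        np.testing.assert_allclose(a, [-3.0, 1.0])
        assert 1 * a[0] + 3 * a[1] == pytest.approx(0.0)
        np.testing.assert_allclose(b, 0.0, atol=1e-15)
        np.testing.assert_allclose(g, 0.0, atol=1e-15)

    def test_constraints_hold_for_random_input(self):
        rng = np.random.default_rng(0)
        n_d = np.array([3, 4, 5])
        eta = rng.normal(0, 2, (3, 40))
        mu, a, b, g = moment_effects(eta, n_d)
        assert n_d @ a == pytest.approx(0.0, abs=1e-10)
        assert b.sum() == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(n_d @ g, 0.0, atol=1e-10)
        np.testing.assert_allclose(g.sum(axis=1), 0.0, atol=1e-10)


class TestWlsRank1:
    def test_exact_two_by_two(self):
        u, v, trace, conv = wls_rank1(np.array([[-1.0, 1.0], [1.0, -1.0]]), [1, 1])
        np.testing.assert_allclose(u, [1.0, -1.0], atol=1e-12)
        np.testing.assert_allclose(v, [-1.0, 1.0], atol=1e-12)
        assert trace[-1] == pytest.approx(0.0, abs=1e-20)
        assert conv

    def test_d2_always_exact_rank1(self):
        rng = np.random.default_rng(1)
        n_d = np.array([2, 5])
        gamma = _random_gamma(rng, 2, 30, n_d)
        u, v, trace, _ = wls_rank1(gamma, n_d)
        np.testing.assert_allclose(gamma, np.outer(u, v), atol=1e-10)

    @pytest.mark.parametrize("D,G,seed", [(3, 25, 0), (4, 50, 1), (5, 100, 2)])
    def test_matches_svd_oracle(self, D, G, seed):
        rng = np.random.default_rng(seed)
        n_d = rng.integers(2, 7, D)
        gamma = _random_gamma(rng, D, G, n_d)
        u, v, trace, conv = wls_rank1(gamma, n_d)
        _, _, obj_oracle = rank1_svd_oracle(gamma, n_d)
        assert conv
        assert trace[-1] == pytest.approx(obj_oracle, abs=1e-8)

    def test_power_iteration_init_agrees_with_svd_init(self):
        rng = np.random.default_rng(3)
        n_d = np.array([4, 4, 4])
        gamma = _random_gamma(rng, 3, 60, n_d)
        u1, v1, t1, _ = wls_rank1(gamma, n_d, init="svd")
        u2, v2, t2, _ = wls_rank1(gamma, n_d, init="means")
        assert t1[-1] == pytest.approx(t2[-1], rel=1e-8)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(4)
        n_d = np.array([3, 4, 5, 6])
        gamma = _random_gamma(rng, 4, 200, n_d)
        _, _, trace, _ = wls_rank1(gamma, n_d, init="means")
        assert np.all(np.diff(trace) <= 1e-12)

    def test_u_v_constraints_automatic(self):
        rng = np.random.default_rng(5)
        n_d = np.array([2, 3, 4])
        gamma = _random_gamma(rng, 3, 40, n_d)
        u, v, _, _ = wls_rank1(gamma, n_d)
        assert u[0] == 1.0
        assert n_d @ u == pytest.approx(0.0, abs=1e-8)
        assert v.sum() == pytest.approx(0.0, abs=1e-8)

    def test_zero_gamma_raises(self):
        with pytest.raises(DegenerateInteractionError):
            wls_rank1(np.zeros((3, 10)), [2, 2, 2])

    def test_gene_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        n_d = np.array([4, 4, 4])
        gamma = _random_gamma(rng, 3, 30, n_d)
        perm = rng.permutation(30)
        u1, v1, _, _ = wls_rank1(gamma, n_d)
        u2, v2, _, _ = wls_rank1(gamma[:, perm], n_d)
        np.testing.assert_allclose(u1, u2, atol=1e-7)
        np.testing.assert_allclose(v1[perm], v2, atol=1e-7)


class TestRefineU:
    def test_all_genes_reduces_to_plain_update(self):
        rng = np.random.default_rng(7)
        n_d = np.array([3, 3, 3])
        gamma = _random_gamma(rng, 3, 20, n_d)
        u, v, _, _ = wls_rank1(gamma, n_d)
        np.testing.assert_allclose(
            refine_u(gamma, n_d, v, np.arange(20)), u, atol=1e-12
        )

    def test_singleton_set_collapses_to_ratio(self):
        rng = np.random.default_rng(8)
        n_d = np.array([2, 2, 2])
        gamma = _random_gamma(rng, 3, 10, n_d)
        v = rng.normal(0, 1, 10)
        g = 4
        u = refine_u(gamma, n_d, v, np.array([g]))
        expect = gamma[:, g] / v[g]
        np.testing.assert_allclose(u, expect / expect[0], atol=1e-12)

    def test_restriction_to_signal_genes_reduces_u_variance(self):
        # 90% of genes carry no interaction and contribute only noise to the
        # u-update; restricting the sums to the signal genes denoises u
        rng = np.random.default_rng(9)
        D, G, n_null = 3, 300, 270
        n_d = np.array([4, 4, 4])
        u_true = np.array([1.0, 0.2, -1.2])
        v_true = np.concatenate([np.zeros(n_null), rng.normal(0, 0.6, G - n_null)])
        errs_full, errs_sub = [], []
        for rep in range(150):
            noise = rng.normal(0, 0.5, (D, G)) / np.sqrt(n_d)[:, None]
            gamma_hat = moment_effects(
                np.outer(u_true, v_true) + noise, n_d
            )[3]
            _, v_hat, _, _ = wls_rank1(gamma_hat, n_d)
            u_full = refine_u(gamma_hat, n_d, v_hat, np.arange(G))
            u_sub = refine_u(gamma_hat, n_d, v_hat, np.arange(n_null, G))
            errs_full.append(u_full - u_true)
            errs_sub.append(u_sub - u_true)
        var_full = np.var(np.array(errs_full), axis=0).sum()
        var_sub = np.var(np.array(errs_sub), axis=0).sum()
        assert var_sub <= var_full


class TestFullFit:
    def test_de_set_all_equals_default(self):
        cm, _ = simulate_rank1(SimConfig(D=3, G=500, seed=11))
        nc = normalize(cm, "median")
        f1 = fit(nc)
        f2 = fit(nc, de_set=np.ones(500, dtype=bool))
        np.testing.assert_allclose(f1.u, f2.u)
        np.testing.assert_allclose(f1.v, f2.v)

    def test_constraint_identities_after_fit(self):
        cm, _ = simulate_rank1(SimConfig(D=4, G=800, seed=12))
        f = fit(normalize(cm, "median"))
        n_d = f.n_d
        assert n_d @ f.alpha == pytest.approx(0.0, abs=1e-8)
        assert f.beta.sum() == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(n_d @ f.gamma, 0.0, atol=1e-8)
        np.testing.assert_allclose(f.gamma.sum(axis=1), 0.0, atol=1e-8)
        assert f.u[0] == 1.0
        assert n_d @ f.u == pytest.approx(0.0, abs=1e-8)
        assert f.v.sum() == pytest.approx(0.0, abs=1e-8)

    def test_recovers_u_on_simulated_data(self):
        cm, truth = simulate_rank1(SimConfig(D=3, G=10_000, seed=13))
        f = fit(normalize(cm, "median"))
        np.testing.assert_allclose(f.u, truth.u, atol=0.25)
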