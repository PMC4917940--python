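import numpy as np
import pytest

from multide import (
    SimConfig,
    simulate_rank1,
    simulate_saturated,
    spike_in_perturbation,
)
from multide.data import CountMatrix
from multide.errors import ConfigError
from multide.normalize import SizeFactors, normalize_counts


class TestConfig:
    def test_default_sample_sizes(self):
        assert list(SimConfig(D=4, design="matched").sizes) == [4, 4, 4, 4]
        assert list(SimConfig(D=4, design="unmatched").sizes) == [4, 5, 6, 7]

    def test_default_u_satisfies_constraints(self):
        for design in ("matched", "unmatched"):
            for D in (2, 3, 4, 5):
                cfg = SimConfig(D=D, design=design)
                u = cfg.resolved_u()
                assert u[0] == 1.0
                assert cfg.sizes @ u == pytest.approx(0.0, abs=1e-12)

    def test_invalid_u_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(D=3, u=(1.0, 1.0, 1.0)).resolved_u()
        with pytest.raises(ConfigError):
            SimConfig(D=3, u=(2.0, 0.4, -2.4)).resolved_u()

    def test_gene_class_counts_must_sum_to_G(self):
        with pytest.raises(ConfigError):
            SimConfig(G=100, n_ee=90, n_up=20, n_down=20)

    def test_v_scale_interpretation(self):
        assert SimConfig(v_scale=0.32).v_sd == pytest.approx(np.sqrt(0.32))
        assert SimConfig(v_scale=0.32, v_scale_is_sd=True).v_sd == 0.32


def test_same_seed_bit_identical():
    for gen in (simulate_rank1, simulate_saturated):
        cm1, t1 = gen(SimConfig(D=3, G=300, seed=42))
        cm2, t2 = gen(SimConfig(D=3, G=300, seed=42))
        np.testing.assert_array_equal(cm1.counts, cm2.counts)
        np.testing.assert_array_equal(t1.delta, t2.delta)
        np.testing.assert_array_equal(t1.phi, t2.phi)
    cm3, _ = simulate_rank1(SimConfig(D=3, G=300, seed=43))
    assert (cm1.counts != cm3.counts).any()


def test_truth_satisfies_model_constraints():
    cfg = SimConfig(D=4, G=400, seed=0)
    _, truth = simulate_rank1(cfg)
    n_d = cfg.sizes
    assert n_d @ truth.alpha == pytest.approx(0.0)
    np.testing.assert_allclose(n_d @ truth.gamma, 0.0, atol=1e-10)
    assert truth.u[0] == 1.0
    assert n_d @ truth.u == pytest.approx(0.0, abs=1e-10)
    # DE labels consistent with v: v = 0 iff EE; signs as specified
    assert np.all((truth.v == 0) == (truth.de_label == "EE"))
    assert np.all(truth.v[truth.de_label == "up"] <= 0)
    assert np.all(truth.v[truth.de_label == "down"] >= 0)


def test_mean_and_variance_match_model():
    # many matched subjects so per-cell empirical moments are tight
    cfg = SimConfig(D=3, G=40, n=10_000, seed=1, n_ee=36, n_up=2, n_down=2)
    cm, truth = simulate_rank1(cfg)
    sf = SizeFactors(truth.delta, "median", cm.sample_ids)
    nc = normalize_counts(cm, sf)  # Y = [X / true delta]
    mu_dg = truth.mu_dg
    for d in range(1, 4):
        blk = nc.values[:, nc.matrix.condition_columns(d)]
        np.testing.assert_allclose(blk.mean(axis=1), mu_dg[d - 1], rtol=0.02)
        expect_var = mu_dg[d - 1] + truth.phi * mu_dg[d - 1] ** 2
        np.testing.assert_allclose(blk.var(axis=1), expect_var, rtol=0.15)


def test_standardized_residuals_pooled_moments():
    cfg = SimConfig(D=3, G=2000, seed=2)
    cm, truth = simulate_rank1(cfg)
    nc = normalize_counts(cm, SizeFactors(truth.delta, "median", cm.sample_ids))
    mu = truth.mu_dg[nc.matrix.conditions - 1].T  # (G, N)
    resid = (nc.values - mu) / np.sqrt(mu + truth.phi[:, None] * mu**2)
    assert abs(resid.mean()) < 0.02
    assert resid.var() == pytest.approx(1.0, rel=0.05)


def test_copula_correlation_calibration():
    # fixed rho = 0.3; latent Z standardized by its population moments and
    # pooled across subjects x genes estimates the pairwise correlation
    cfg = SimConfig(D=3, G=500, n=60, seed=3, rho_range=(0.3, 0.3),
                    keep_latent=True)
    cm, truth = simulate_rank1(cfg)
    Z = truth.latent  # (G, N)
    sd = truth.phi[None, :] ** 0.5 * truth.mu_dg  # gamma sd per (d, g)
    for d1, d2 in [(0, 1), (0, 2), (1, 2)]:
        z1 = (Z[:, cm.condition_columns(d1 + 1)] - truth.mu_dg[d1][:, None]) / sd[d1][:, None]
        z2 = (Z[:, cm.condition_columns(d2 + 1)] - truth.mu_dg[d2][:, None]) / sd[d2][:, None]
        r = np.mean(z1 * z2) / np.sqrt(np.mean(z1**2) * np.mean(z2**2))
        assert r == pytest.approx(0.3, abs=0.05)


class TestSaturated:
    def test_degenerate_range_gives_all_ee_interactions(self):
        _, truth = simulate_saturated(SimConfig(D=3, G=200, seed=4),
                                      gamma_range=(0.0, 0.0))
        np.testing.assert_array_equal(truth.gamma, 0.0)

    def test_interactions_not_rank_one(self):
        cfg = SimConfig(D=4, G=300, seed=5)
        _, truth = simulate_saturated(cfg)
        de_block = truth.gamma[:, truth.de_label == "DE"]
        assert np.linalg.matrix_rank(de_block, tol=1e-8) > 1

    def test_recentring_constraint_holds(self):
        cfg = SimConfig(D=3, design="unmatched", G=300, seed=6)
        _, truth = simulate_saturated(cfg)
        np.testing.assert_allclose(cfg.sizes @ truth.gamma, 0.0, atol=1e-10)


class TestSpikeIn:
    def _base(self, G=50, N=9, seed=0):
        rng = np.random.default_rng(seed)
        return CountMatrix(
            counts=rng.poisson(60, (G, N)),
            gene_ids=[f"g{i}" for i in range(G)],
            sample_ids=[f"s{j}" for j in range(N)],
            conditions=[1] * 5 + [2] * (N - 5),
        )

    def test_multiplication_rounds_to_nearest(self):
        cm = self._base()
        cm.counts[:] = 10
        out, truth = spike_in_perturbation(cm, D=3, de_count=50, seed=1)
        de_rows = out.counts[truth.de_label == "DE"]
        for d, expect in [(1, 10), (2, 11), (3, 9)]:
            cols = out.conditions == d
            assert np.all(de_rows[:, cols] == expect)

    def test_unit_factors_change_nothing_but_labels(self):
        cm = self._base()
        out, _ = spike_in_perturbation(cm, D=3, de_count=10,
                                       factors=(1.0, 1.0, 1.0), seed=2)
        np.testing.assert_array_equal(out.counts, cm.counts)

    def test_exact_de_count(self):
        cm = self._base(G=6526, N=9, seed=3)
        out, truth = spike_in_perturbation(cm, D=3, de_count=600, seed=4)
        assert int((truth.de_label == "DE").sum()) == 600
        assert list(out.n_d) == [3, 3, 3]

    def test_invalid_configs(self):
        cm = self._base()
        with pytest.raises(ConfigError):
            spike_in_perturbation(cm, D=2, de_count=5, seed=0)  # 9 % 2 != 0
        with pytest.raises(ConfigError):
            spike_in_perturbation(cm, D=3, de_count=10_000, seed=0)
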