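import numpy as np
import pytest
from scipy import integrate, stats

from gxeset import (
    ResamplingConfig,
    adabf_test,
    bayes_factor,
    cumulative_log_bf,
    null_interaction_covariance,
    sample_null_S,
    simulate_genotypes,
)
from gxeset.adabf import bayes_factor_set, derive_gene_seed
from gxeset.glm_engine import batch_interaction_fits
from gxeset.sim_engine import simulate_null_phenotype


def numeric_bf(beta_hat: float, v_hat: float, W: float) -> float:
    """Independent oracle: the marginal-to-null density ratio by quadrature."""
    num, _ = integrate.quad(
        lambda b: stats.norm.pdf(beta_hat, b, np.sqrt(v_hat)) * stats.norm.pdf(b, 0, np.sqrt(W)),
        -10 * np.sqrt(W), 10 * np.sqrt(W), epsabs=1e-14, limit=500)
    return num / stats.norm.pdf(beta_hat, 0, np.sqrt(v_hat))


class TestBayesFactor:
    def test_zero_estimate_shrinkage(self):
        assert bayes_factor(0.0, 0.04, 0.04) == pytest.approx(np.sqrt(0.5), rel=1e-12)

    def test_against_integration_oracle(self):
        """Closed form equals the numerically integrated likelihood ratio."""
        for beta in (-0.5, -0.2, 0.0, 0.1, 0.2, 0.4):
            for v in (0.001, 0.01, 0.1):
                for W in (0.01, 0.04):
                    assert bayes_factor(beta, v, W) == pytest.approx(
                        numeric_bf(beta, v, W), rel=1e-6)

    def test_frozen_oracle_value(self):
        # quadrature oracle value for (0.2, 0.01, 0.04), frozen:
        # sqrt(0.01/0.05) * exp(0.2^2 * 0.04 / (2 * 0.01 * 0.05)) = 2.215063
        assert bayes_factor(0.2, 0.01, 0.04) == pytest.approx(2.215063, abs=5e-6)
        assert numeric_bf(0.2, 0.01, 0.04) == pytest.approx(2.215063, abs=5e-6)

    def test_monotone_in_abs_beta(self):
        assert bayes_factor(0.4, 0.01, 0.04) > bayes_factor(0.2, 0.01, 0.04)
        assert bayes_factor(-0.3, 0.01, 0.04) == pytest.approx(
            bayes_factor(0.3, 0.01, 0.04), rel=1e-12)

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            bayes_factor(0.1, 0.0, 0.04)
        with pytest.raises(ValueError):
            bayes_factor(0.1, 0.01, -1.0)


class TestCumulativeLogBF:
    def test_powers_of_e(self):
        S = cumulative_log_bf(np.array([np.e, 1.0, np.e ** 2]))
        np.testing.assert_allclose(S, [2, 3, 3], atol=1e-12)

    def test_single_and_null(self):
        np.testing.assert_allclose(cumulative_log_bf(np.array([2.0])), [np.log(2)])
        np.testing.assert_allclose(cumulative_log_bf(np.ones(4)), np.zeros(4), atol=1e-12)

    def test_concave_increments(self, rng):
        bfs = np.exp(rng.standard_normal(15))
        S = cumulative_log_bf(bfs)
        inc = np.diff(np.concatenate([[0.0], S]))
        assert np.all(np.diff(inc) <= 1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cumulative_log_bf(np.array([]))


class TestNullCovariance:
    def test_scalar_case(self, null_data):
        Y, G, E = null_data
        sigma = null_interaction_covariance(G[:, :1], E, None, "gaussian", [0.02])
        np.testing.assert_allclose(sigma, [[0.02]], rtol=1e-12)

    def test_duplicated_snp_perfect_ld(self, null_data):
        Y, G, E = null_data
        g = G[:, [0, 0]]
        sigma = null_interaction_covariance(g, E, None, "gaussian", [0.03, 0.03])
        corr = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
        assert corr == pytest.approx(1.0, abs=1e-8)
        assert np.min(np.linalg.eigvalsh(sigma)) >= -1e-12

    def test_independent_snps_small_offdiag(self):
        gm = simulate_genotypes(5000, 8, ld_rho=0.0, seed=9)
        rng = np.random.default_rng(10)
        E = rng.binomial(1, 0.5, 5000).astype(float)
        v = np.full(8, 0.01)
        sigma = null_interaction_covariance(gm.counts, E, None, "gaussian", v)
        corr = sigma / 0.01
        off = corr[~np.eye(8, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.05

    def test_empty_window_errors(self, null_data):
        Y, G, E = null_data
        with pytest.raises(ValueError):
            null_interaction_covariance(G[:, :0], E, None, "gaussian", [])


class TestSampleNullS:
    def test_reproducible_and_centered(self):
        sigma = np.array([[0.04, 0.01], [0.01, 0.04]])
        a = sample_null_S(sigma, 0.04, 500, seed=3)
        b = sample_null_S(sigma, 0.04, 500, seed=3)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (500, 2)

    def test_scalar_quantiles_match_mc_oracle(self):
        """Empirical S_1 distribution matches a direct scalar Monte-Carlo."""
        v, W = 0.04, 0.04
        draws = sample_null_S(np.array([[v]]), W, 20000, seed=4)[:, 0]
        rng = np.random.default_rng(5)
        beta = rng.normal(0, np.sqrt(v), 200000)
        oracle = 0.5 * np.log(v / (v + W)) + beta ** 2 * W / (2 * v * (v + W))
        ks = stats.ks_2samp(draws, oracle)
        assert ks.pvalue > 0.01


class TestAdabfTest:
    def test_early_stop_at_bmin(self, null_data):
        Y, G, E = null_data
        res = adabf_test(Y, G, E, cfg=ResamplingConfig(seed=1))
        # a typical null gene has p well above 0.1, so B stays at b_min
        assert res.b_used == 1000
        assert 0 < res.p_value <= 1
        assert 1 <= res.best_k <= G.shape[1]

    def test_snp_order_invariance(self, null_data):
        Y, G, E = null_data
        cfg = ResamplingConfig(seed=7)
        p1 = adabf_test(Y, G, E, cfg=cfg).p_value
        perm = np.random.default_rng(0).permutation(G.shape[1])
        p2 = adabf_test(Y, G[:, perm], E, cfg=cfg).p_value
        assert p1 == p2

    def test_allele_flip_invariance(self, null_data):
        Y, G, E = null_data
        cfg = ResamplingConfig(seed=7)
        p1 = adabf_test(Y, G, E, cfg=cfg).p_value
        G2 = G.copy()
        G2[:, 0] = 2 - G2[:, 0]
        p2 = adabf_test(Y, G2, E, cfg=cfg).p_value
        assert p1 == pytest.approx(p2, abs=0.02)

    def test_sequential_escalates_for_strong_signal(self):
        gm = simulate_genotypes(800, 6, seed=13)
        rng = np.random.default_rng(14)
        E = rng.binomial(1, 0.5, 800).astype(float)
        Y = 0.6 * gm.counts[:, 2] * E + rng.standard_normal(800)
        res = adabf_test(Y, gm.counts, E, cfg=ResamplingConfig(seed=2, b_max=100_000))
        assert res.b_used > 1000
        assert res.p_value < 0.01

    def test_all_degenerate_returns_reason(self, null_data):
        Y, G, E = null_data
        Gd = np.zeros_like(G)
        res = adabf_test(Y, Gd, E)
        assert res.p_value is None
        assert "degenerate" in res.diagnostics["reason"]

    def test_per_k_pvalues_uniform_under_null(self):
        """Marginal per-k resampling p-values are uniform under H0."""
        gm = simulate_genotypes(300, 5, seed=21)
        rng = np.random.default_rng(22)
        cfg_template = ResamplingConfig(b_min=500, b_max=500)
        pk = []
        for rep in range(800):
            Y, E = simulate_null_phenotype(300, "gaussian", rng)
            cfg = ResamplingConfig(500, 500, 100, seed=int(rng.integers(2 ** 31)))
            res = adabf_test(Y, gm.counts, E, cfg=cfg)
            pk.append(res.diagnostics["per_k_p"])
        pk = np.array(pk)
        for k in range(pk.shape[1]):
            assert stats.kstest(pk[:, k], "uniform").pvalue > 0.001

    def test_w_robustness_null_calibration(self):
        """Different prior variances give different BFs but both stay valid."""
        gm = simulate_genotypes(300, 5, seed=31)
        rng = np.random.default_rng(32)
        ps = {0.01: [], 0.04: []}
        for rep in range(300):
            Y, E = simulate_null_phenotype(300, "gaussian", rng)
            seed = int(rng.integers(2 ** 31))
            for W in ps:
                cfg = ResamplingConfig(400, 400, 100, seed=seed)
                ps[W].append(adabf_test(Y, gm.counts, E, W=W, cfg=cfg).p_value)
        for W, vals in ps.items():
            assert 0.01 < np.mean(np.array(vals) <= 0.05) < 0.12

    def test_gene_seed_derivation(self):
        s1 = derive_gene_seed(1, "GENE_A")
        s2 = derive_gene_seed(1, "GENE_B")
        assert s1 != s2
        assert 0 <= s1 < 2 ** 31
        assert derive_gene_seed(1, "GENE_A") == s1
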