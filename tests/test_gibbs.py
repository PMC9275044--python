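"""Gibbs sampler: mixed-model-equation conditionals, inverse-Wishart
updates and agreement with the NUTS sampler under a shared prior."""
import numpy as np
import pytest
from scipy import stats
from scipy.stats import invwishart

from mtvc.genotypes import compute_grm, qc_filter, synthetic_genotypes
from mtvc.gibbs import (
    GibbsConfig,
    conditional_location_mean,
    run_gibbs,
    sample_genetic_covariance,
    sample_location,
    sample_residual_covariance,
)
from mtvc.model import PriorConfig
from mtvc.nuts import NUTSConfig
from mtvc.experiment import fit_nuts
from mtvc.simulate import default_architecture, simulate_traits


def _batch_se(x: np.ndarray, n_batches: int = 40) -> float:
    """Batch-means Monte-Carlo standard error of a chain mean."""
    n = len(x) // n_batches * n_batches
    means = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


class TestLocationConditional:
    def test_zero_phenotypes_zero_mean(self):
        y = np.zeros((6, 2))
        mu, a = conditional_location_mean(y, np.eye(2), np.eye(2), np.eye(6))
        assert np.abs(mu).max() < 1e-12
        assert np.abs(a).max() < 1e-12

    def test_single_trait_identity_kinship_is_ridge(self, rng):
        """With A = I and mu fixed, the a-conditional mean is the ridge
        shrinkage (1 + sigma_e^2/sigma_a^2)^{-1} (y - mu)."""
        n = 8
        y = rng.standard_normal((n, 1)) * 2.0
        s2a, s2e = 1.5, 3.0
        mu = np.array([0.4])
        _, a = conditional_location_mean(
            y, np.array([[s2a]]), np.array([[s2e]]), np.eye(n), mu=mu
        )
        lam = s2e / s2a
        ridge = (y - mu) / (1.0 + lam)
        assert np.abs(a - ridge).max() <= 1e-10

    def test_joint_mean_matches_dense_mme_oracle(self, rng):
        """Independent dense solver of Henderson's equations on an
        n = 5, t = 2 toy (trait-major stacking, X = I_t (x) 1)."""
        n, t = 5, 2
        B = rng.standard_normal((n, n))
        A = B @ B.T + n * np.eye(n)
        y = rng.standard_normal((n, t))
        G0 = np.array([[1.0, 0.3], [0.3, 2.0]])
        R0 = np.array([[2.0, -0.4], [-0.4, 1.5]])
        mu_mean, a_mean = conditional_location_mean(y, G0, R0, A)

        Rinv = np.kron(np.linalg.inv(R0), np.eye(n))
        Ginv = np.kron(np.linalg.inv(G0), np.linalg.inv(A))
        X = np.kron(np.eye(t), np.ones((n, 1)))
        Z = np.eye(n * t)
        yv = y.T.ravel()  # trait-major
        C = np.block(
            [
                [X.T @ Rinv @ X, X.T @ Rinv @ Z],
                [Z.T @ Rinv @ X, Z.T @ Rinv @ Z + Ginv],
            ]
        )
        rhs = np.concatenate([X.T @ Rinv @ yv, Z.T @ Rinv @ yv])
        sol = np.linalg.solve(C, rhs)
        assert np.abs(mu_mean - sol[:t]).max() <= 1e-10
        assert np.abs(a_mean.T.ravel() - sol[t:]).max() <= 1e-10

    def test_sample_location_centers_on_conditional_mean(self, rng):
        n, t = 6, 2
        y = rng.standard_normal((n, t))
        G0, R0 = np.eye(t), np.eye(t)
        A = np.eye(n)
        mu_mean, a_mean = conditional_location_mean(y, G0, R0, A)
        draws = [sample_location(y, G0, R0, A, rng) for _ in range(4000)]
        mu_bar = np.mean([d[0] for d in draws], axis=0)
        a_bar = np.mean([d[1] for d in draws], axis=0)
        assert np.abs(mu_bar - mu_mean).max() < 0.05
        assert np.abs(a_bar - a_mean).max() < 0.05


class TestCovarianceConditionals:
    def test_posterior_degrees_of_freedom_bookkeeping(self, rng):
        # with e = 0 the scale stays at the prior scale and df = v_E + n
        n, t, v = 50, 2, 7.0
        draws = np.stack(
            [
                sample_residual_covariance(np.zeros((n, t)), None, v, rng)
                for _ in range(6000)
            ]
        )
        expected_mean = np.eye(t) / (v + n - t - 1)
        assert np.abs(draws.mean(axis=0) - expected_mean).max() < 0.002

    def test_prior_only_moment_formula(self, rng):
        """With no data rows the genetic-covariance update reduces to the
        prior: IW(df = 7, scale = I) in t = 2 has mean I / (7 - 2 - 1)."""
        t, v = 2, 7.0
        a_empty = np.zeros((0, t))
        A_empty = np.eye(0)
        draws = np.stack(
            [
                sample_genetic_covariance(a_empty, A_empty, None, v, rng)
                for _ in range(8000)
            ]
        )
        assert np.abs(draws.mean(axis=0) - 0.25 * np.eye(t)).max() < 0.02

    def test_conjugacy_matches_direct_posterior_draws(self, rng):
        """With a fixed, known a, sampled G0 must match direct IW draws
        from the analytic posterior (two-sample KS on each element)."""
        n, t, v = 200, 2, 2.0
        a = rng.standard_normal((n, t)) @ np.linalg.cholesky(
            np.array([[1.0, 0.5], [0.5, 2.0]])
        ).T
        eye_eig = (np.ones(n), np.eye(n))  # precomputed identity kinship
        ours = np.stack(
            [
                sample_genetic_covariance(a, eye_eig, None, v, rng)
                for _ in range(4000)
            ]
        )
        direct = invwishart.rvs(
            df=v + n, scale=np.eye(t) + a.T @ a, size=4000, random_state=rng
        )
        for i in range(t):
            for j in range(i + 1):
                p = stats.ks_2samp(ours[:, i, j], direct[:, i, j]).pvalue
                assert p > 1e-3

    def test_large_n_consistency(self, rng):
        n, t = 2000, 2
        G0_true = np.array([[1.0, 0.4], [0.4, 2.0]])
        a = rng.standard_normal((n, t)) @ np.linalg.cholesky(G0_true).T
        eye_eig = (np.ones(n), np.eye(n))
        draws = np.stack(
            [
                sample_genetic_covariance(a, eye_eig, None, float(t), rng)
                for _ in range(200)
            ]
        )
        assert np.abs(draws.mean(axis=0) - G0_true).max() < 0.1 * np.abs(G0_true).max() + 0.05


class TestRunGibbs:
    def test_kept_draw_counts(self):
        cfg = GibbsConfig()
        assert (cfg.n_iter - cfg.burn_in) // cfg.thin == 900
        rng = np.random.default_rng(0)
        y = rng.standard_normal((10, 2))
        out = run_gibbs(y, np.eye(10), GibbsConfig(n_iter=200, burn_in=0, thin=1, seed=1))
        assert out.n_kept == 200
        out2 = run_gibbs(y, np.eye(10), GibbsConfig(n_iter=200, burn_in=50, thin=5, seed=1))
        assert out2.n_kept == 30

    def test_all_kept_covariances_spd(self, rng):
        y = rng.standard_normal((15, 2))
        out = run_gibbs(y, np.eye(15), GibbsConfig(n_iter=300, burn_in=50, thin=5, seed=3))
        for k in range(out.n_kept):
            assert np.linalg.eigvalsh(out.G0[k])[0] > 0
            assert np.linalg.eigvalsh(out.R0[k])[0] > 0

    def test_deterministic_given_seed(self, rng):
        y = rng.standard_normal((10, 2))
        a = run_gibbs(y, np.eye(10), GibbsConfig(n_iter=100, burn_in=10, thin=2, seed=5))
        b = run_gibbs(y, np.eye(10), GibbsConfig(n_iter=100, burn_in=10, thin=2, seed=5))
        assert np.array_equal(a.G0, b.G0)
        assert np.array_equal(a.a, b.a)

    def test_stationary_recovery_on_simulated_data(self):
        """Posterior means track the simulation truth on a moderately
        informative dataset."""
        g = synthetic_genotypes(200, 2000, n_families=40, seed=8)
        g, _ = qc_filter(g)
        rel = compute_grm(g)
        arch = default_architecture()
        ds = simulate_traits(rel, arch, seed=21)
        out = run_gibbs(
            ds.y, rel.A, GibbsConfig(n_iter=4000, burn_in=1000, thin=3, seed=2)
        )
        R0_hat = out.R0.mean(axis=0)
        # residual variances carry most information at n = 200
        assert np.abs(np.diag(R0_hat) - np.diag(arch.R0)).max() < 3.0

    def test_cross_sampler_agreement_with_nuts_iw(self):
        """NUTS under the transported IW prior and the conjugate Gibbs
        sampler target the same posterior: compare all covariance means
        on an n = 30 toy within 3 combined Monte-Carlo SEs."""
        g = synthetic_genotypes(30, 800, n_families=6, seed=2)
        g, _ = qc_filter(g)
        rel = compute_grm(g)
        ds = simulate_traits(rel, default_architecture(), seed=11)
        fn = fit_nuts(
            ds.y, rel.A, PriorConfig(kind="iw"),
            NUTSConfig(n_iter=6000, n_warmup=2000, target_accept=0.95, seed=1),
            seed=1,
        )
        fg = run_gibbs(
            ds.y, rel.A, GibbsConfig(n_iter=30000, burn_in=3000, thin=3, seed=1)
        )
        for mats_n, mats_g in ((fn.G0_draws, fg.G0), (fn.R0_draws, fg.R0)):
            for i in range(2):
                for j in range(i + 1):
                    xn = mats_n[:, i, j]
                    xg = mats_g[:, i, j]
                    se = np.hypot(_batch_se(xn), _batch_se(xg))
                    assert abs(xn.mean() - xg.mean()) <= 3.0 * se, (i, j)
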