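"""Hierarchical-model densities, R-hat diagnostics, and sampler correctness."""

import math

import arviz as az
import numpy as np
import pytest
from scipy import stats

from nanopbpk import (
    HierarchicalPriors,
    MCMCConfig,
    ObservationRecord,
    Route,
    joint_log_density,
    log_hyperprior,
    log_likelihood,
    log_population,
    rhat,
    run_mcmc,
    summarize_posterior,
)
from nanopbpk.calibration import _cpc_log_prior, chol_from_cpc, lkj_logpdf


def _obs(value, study="s1", time=1.0):
    return ObservationRecord(
        study=study, route=Route.IV, tissue="liver", time_h=time,
        dose_ug=10.0, value=value,
    )


def _identity_forward(theta, study, records):
    return np.full(len(records), theta[0])


class TestLogLikelihood:
    def test_zero_residual_unit_sigma(self):
        ll = log_likelihood([_obs(2.0)], {"s1": np.array([2.0])}, 1.0, _identity_forward)
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_matches_normal_density_oracle(self):
        # single obs, sigma 0.5, log-residual 0.5 -> z = 1
        f = 3.0
        y = f * math.exp(0.5)
        ll = log_likelihood([_obs(y)], {"s1": np.array([f])}, 0.5, _identity_forward)
        assert ll == pytest.approx(stats.norm.logpdf(math.log(y), math.log(f), 0.5))

    def test_additive_over_observations(self):
        one = log_likelihood([_obs(2.5)], {"s1": np.array([2.0])}, 0.4, _identity_forward)
        two = log_likelihood(
            [_obs(2.5), _obs(2.5, time=24.0)], {"s1": np.array([2.0])}, 0.4,
            _identity_forward,
        )
        assert two == pytest.approx(2 * one)

    def test_nonpositive_prediction_names_record(self):
        with pytest.raises(ValueError, match="liver"):
            log_likelihood([_obs(2.0)], {"s1": np.array([0.0])}, 1.0, _identity_forward)


class TestLogPopulation:
    def test_standard_normal_at_mean(self):
        lp = log_population(np.zeros((3, 1)), np.zeros(1), np.eye(1))
        assert lp == pytest.approx(3 * -0.5 * math.log(2 * math.pi))

    def test_diagonal_factorizes(self, rng):
        p, n = 4, 6
        mu = rng.normal(size=p)
        sd = rng.uniform(0.5, 2.0, size=p)
        theta = rng.normal(size=(n, p))
        lp = log_population(theta, mu, np.diag(sd**2))
        oracle = sum(
            stats.norm.logpdf(theta[i, k], mu[k], sd[k])
            for i in range(n) for k in range(p)
        )
        assert lp == pytest.approx(oracle, rel=1e-12)

    def test_permutation_invariance(self, rng):
        p = 3
        mu = rng.normal(size=p)
        a = rng.normal(size=(p, p))
        cov = a @ a.T + p * np.eye(p)
        theta = rng.normal(size=(5, p))
        perm = [2, 0, 1]
        lp = log_population(theta, mu, cov)
        lp_perm = log_population(
            theta[:, perm], mu[perm], cov[np.ix_(perm, perm)]
        )
        assert lp_perm == pytest.approx(lp, rel=1e-12)

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            log_population(np.zeros((2, 2)), np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestLogHyperprior:
    def _priors(self, p=1, a=2.0):
        return HierarchicalPriors(
            monitored_names=tuple(f"p{i}" for i in range(p)),
            hyper_mean=np.zeros(p),
            hyper_sd=np.ones(p),
            lkj_shape=a,
        )

    def test_degenerate_dimension_reduces_to_mu_s_sigma_terms(self):
        pri = self._priors(p=1)
        lp = log_hyperprior(np.array([0.3]), np.array([0.5]), np.eye(1), 0.4, pri)
        expected = (
            stats.norm.logpdf(0.3, 0, 1)
            + stats.halfnorm.logpdf(0.5, scale=1)
            + stats.halfnorm.logpdf(0.4, scale=1)
        )
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_lkj_uniform_at_shape_one(self):
        pri = self._priors(p=2, a=1.0)
        c1 = np.array([[1.0, 0.3], [0.3, 1.0]])
        c2 = np.array([[1.0, -0.8], [-0.8, 1.0]])
        args = (np.zeros(2), np.ones(2))
        assert log_hyperprior(*args, c1, 0.4, pri) == pytest.approx(
            log_hyperprior(*args, c2, 0.4, pri)
        )

    def test_lkj_2x2_matches_det_power_on_grid(self):
        """LKJ(a) density on 2x2 correlation matrices is (1 - r^2)^(a-1)."""
        a = 2.5
        for r in np.linspace(-0.9, 0.9, 7):
            C = np.array([[1.0, r], [r, 1.0]])
            assert lkj_logpdf(C, a) == pytest.approx((a - 1) * math.log(1 - r**2))

    def test_invalid_diagonal_rejected(self):
        with pytest.raises(ValueError, match="unit diagonal"):
            lkj_logpdf(np.array([[1.0, 0.1], [0.1, 1.1]]), 2.0)


class TestCPCTransform:
    def test_valid_correlation_matrices(self, rng):
        for p in (2, 3, 5, 9):
            z = np.tanh(rng.normal(size=p * (p - 1) // 2))
            L = chol_from_cpc(z, p)
            C = L @ L.T
            np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(C) > 0)

    def test_p2_prior_consistent_with_lkj_density(self):
        """For p=2 the CPC is the correlation itself; the CPC prior plus tanh
        jacobian must equal the LKJ density plus the same jacobian."""
        a = 2.0
        for z in (-0.7, 0.0, 0.5):
            cpc = _cpc_log_prior(np.array([z]), 2, a)
            C = np.array([[1.0, z], [z, 1.0]])
            direct = lkj_logpdf(C, a) + math.log1p(-z**2)  # + tanh jacobian
            assert cpc == pytest.approx(direct, rel=1e-12)


class TestJointDensity:
    def test_sum_of_stages(self, rng):
        obs = [_obs(2.0), _obs(3.0, time=24.0), _obs(1.5, study="s2")]
        theta_tr = {"s1": np.array([0.5]), "s2": np.array([0.2])}
        pri = HierarchicalPriors(("k",), np.zeros(1), np.ones(1))
        mu, s, C, sigma = np.array([0.3]), np.array([0.4]), np.eye(1), 0.5
        total = joint_log_density(obs, theta_tr, mu, s, C, sigma, pri, _identity_forward)
        theta_nat = {k: np.exp(v) for k, v in theta_tr.items()}
        parts = (
            log_likelihood(obs, theta_nat, sigma, _identity_forward)
            + log_population(np.array([theta_tr["s1"], theta_tr["s2"]]), mu,
                             np.diag(s) @ C @ np.diag(s))
            + log_hyperprior(mu, s, C, sigma, pri)
        )
        assert total == pytest.approx(parts, rel=1e-12)


class TestRhat:
    def test_hand_computed_identical_chains(self):
        """Two identical chains [1,2,3,4], unsplit: B = 0, W = 5/3, so
        R-hat = sqrt(3/4)."""
        chains = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        assert rhat(chains, split=False) == pytest.approx(math.sqrt(0.75), abs=1e-12)

    def test_divergent_chains_flagged(self, rng):
        chains = np.vstack([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
        assert rhat(chains) > 1.2

    def test_matches_arviz_split_rhat(self, rng):
        """Agreement with an independent reference implementation to 1e-6."""
        for _ in range(5):
            chains = rng.normal(size=(4, 200)) + rng.normal(size=(4, 1)) * 0.3
            ref = float(az.rhat(az.convert_to_dataset(chains),
                                method="split")["x"].values)
            assert rhat(chains, split=True) == pytest.approx(ref, abs=1e-6)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="within-chain variance"):
            rhat(np.ones((2, 10)))


class TestSummarizePosterior:
    def test_geometric_mean(self):
        draws = np.tile([1.0, 100.0], 60)
        assert summarize_posterior(draws)["geo_mean"] == pytest.approx(10.0)

    def test_constant_draws_unit_gsd(self):
        assert summarize_posterior(np.full(200, 7.0))["gsd"] == pytest.approx(1.0)

    def test_lognormal_gsd_recovered(self, rng):
        draws = rng.lognormal(0.0, 0.5, size=100_000)
        assert summarize_posterior(draws)["gsd"] == pytest.approx(
            math.exp(0.5), rel=0.01
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            summarize_posterior(np.linspace(-1, 1, 200))


def _batch_means_mcse(x: np.ndarray, n_batches: int = 25) -> float:
    n = x.size // n_batches * n_batches
    means = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))


class TestSamplerConjugateCheck:
    def test_identity_forward_matches_analytic_posterior(self, rng):
        """Forward = identity, one group, fixed sigma and population scale:
        the (mu, theta_tr) posterior is jointly Gaussian and the sampler's
        posterior means must match the closed form within 3 MC standard
        errors."""
        sigma0, s0, M, S = 0.3, 0.2, 0.0, 1.0
        truth = math.log(2.0)
        n_obs = 20
        y = np.exp(truth + sigma0 * rng.standard_normal(n_obs))
        obs = [_obs(v, time=float(i + 1)) for i, v in enumerate(y)]
        ybar = float(np.mean(np.log(y)))

        # joint Gaussian precision for (mu, theta_tr)
        lam = np.array(
            [
                [1 / S**2 + 1 / s0**2, -1 / s0**2],
                [-1 / s0**2, 1 / s0**2 + n_obs / sigma0**2],
            ]
        )
        b = np.array([M / S**2, n_obs * ybar / sigma0**2])
        mean_exact = np.linalg.solve(lam, b)

        pri = HierarchicalPriors(("k",), np.array([M]), np.array([S]))
        cfg = MCMCConfig(
            n_chains=4, n_warmup=500, n_samples=2000, seed=7,
            fix_sigma=sigma0, fix_s=s0,
        )
        res = run_mcmc(obs, pri, cfg, _identity_forward)
        mu_draws = res.draws["mu"][:, :, 0].ravel()
        th_draws = res.draws["theta_tr"][:, :, 0, 0].ravel()
        assert abs(mu_draws.mean() - mean_exact[0]) < 3 * _batch_means_mcse(mu_draws)
        assert abs(th_draws.mean() - mean_exact[1]) < 3 * _batch_means_mcse(th_draws)
        assert res.max_rhat < 1.05

    def test_requires_two_chains(self):
        with pytest.raises(ValueError, match="chains"):
            MCMCConfig(n_chains=1)
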