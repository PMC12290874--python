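"""Parameter transforms, annealing prior, simulation, posterior training."""

import numpy as np
import pytest
from scipy import integrate

from sgmfc import (DEFAULT_BANDS, GaussianPrior, SGMParams,
                   annealing_prior, band_fc, from_unbounded,
                   generate_observation, lin_concordance,
                   log_abs_det_jacobian, minmax_vectorize, simulate_pairs,
                   to_unbounded, train_posterior)
from sgmfc.exceptions import DomainError
from sgmfc.inference import LOWER, UPPER, PosteriorEstimate, fit_shared

ALPHA = DEFAULT_BANDS[2]
THETA_STAR = SGMParams(0.015, 12.0, 0.5)


class TestTransforms:
    def test_midpoint_maps_to_origin(self):
        mid = SGMParams(*(0.5 * (LOWER + UPPER)))
        np.testing.assert_allclose(to_unbounded(mid), np.zeros(3), atol=1e-12)

    def test_round_trip(self):
        theta = SGMParams(0.015, 12.0, 0.5)
        back = from_unbounded(to_unbounded(theta)).as_array()
        np.testing.assert_allclose(back, theta.as_array(), atol=1e-12)

    def test_lower_bound_tau_g_rejected(self):
        # the graph time constant's admissible range is [0.005 s, 0.03 s];
        # the boundary itself is not transformable
        with pytest.raises(DomainError, match="tau_g"):
            to_unbounded(np.array([0.005, 12.0, 0.5]))

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            s = rng.normal(0.0, 1.5, size=3)
            theta = from_unbounded(s).as_array()
            eps = 1e-7
            jac = np.zeros((3, 3))
            for k in range(3):
                tp, tm = theta.copy(), theta.copy()
                tp[k] += eps
                tm[k] -= eps
                jac[:, k] = (to_unbounded(tp) - to_unbounded(tm)) / (2 * eps)
            numeric = np.log(np.abs(np.linalg.det(jac)))
            assert log_abs_det_jacobian(s) == pytest.approx(numeric, abs=1e-6)

    def test_inverse_always_inside_bounds(self):
        for s in ([-50.0, 0.0, 50.0], [100.0, -100.0, 0.0]):
            arr = from_unbounded(np.array(s)).as_array()
            assert np.all(arr > LOWER) and np.all(arr < UPPER)


@pytest.fixture(scope="module")
def noiseless_obs(sc8):
    return generate_observation(sc8, THETA_STAR, [ALPHA], noise_sd=0.0,
                                seed=0).band_fcs[0]


class TestAnnealingPrior:
    def test_annealed_loss_at_most_truth_loss(self, sc8, noiseless_obs):
        prior = annealing_prior(noiseless_obs, sc8, n_iter=200, seed=1)
        obs_vec = minmax_vectorize(noiseless_obs)

        def loss(theta):
            return 1 - lin_concordance(
                minmax_vectorize(band_fc(sc8, theta, ALPHA)), obs_vec)

        assert loss(prior.theta_hat) <= loss(THETA_STAR) + 1e-6

    def test_seeded_determinism(self, sc8, noiseless_obs):
        a = annealing_prior(noiseless_obs, sc8, n_iter=20, seed=4)
        b = annealing_prior(noiseless_obs, sc8, n_iter=20, seed=4)
        np.testing.assert_array_equal(a.mean, b.mean)

    def test_identity_covariance(self, sc8, noiseless_obs):
        prior = annealing_prior(noiseless_obs, sc8, n_iter=20, seed=4)
        np.testing.assert_array_equal(prior.cov, np.eye(3))


class TestSimulatePairs:
    def test_noiseless_simulations_deterministic_in_parameters(self, sc8):
        prior = GaussianPrior(mean=np.zeros(3), cov=np.eye(3))
        batch = simulate_pairs(prior, sc8, [ALPHA], M=5, noise_sd=0.0, seed=2)
        for s, mats in zip(batch.s, batch.matrices):
            expected = band_fc(sc8, from_unbounded(s), ALPHA).matrix
            np.testing.assert_array_equal(mats[0], expected)

    def test_sample_mean_near_prior_mean(self, sc8):
        prior = GaussianPrior(mean=np.array([0.5, -0.3, 0.2]), cov=np.eye(3))
        batch = simulate_pairs(prior, sc8, [ALPHA], M=400, noise_sd=0.0, seed=3)
        se = 1.0 / np.sqrt(400)
        assert np.abs(batch.s.mean(axis=0) - prior.mean).max() < 4 * se

    def test_seeded_reproducibility(self, sc8):
        prior = GaussianPrior(mean=np.zeros(3), cov=np.eye(3))
        a = simulate_pairs(prior, sc8, [ALPHA], M=3, noise_sd=0.1, seed=6)
        b = simulate_pairs(prior, sc8, [ALPHA], M=3, noise_sd=0.1, seed=6)
        np.testing.assert_array_equal(a.s, b.s)
        np.testing.assert_array_equal(a.matrices[0][0], b.matrices[0][0])


class TestTrainPosterior:
    def test_recovery_band_specific(self, sc16):
        obs = generate_observation(sc16, THETA_STAR, DEFAULT_BANDS,
                                   noise_sd=0.05, seed=100)
        post = train_posterior(obs.shared, sc16, rounds=2, M=300,
                               noise_sd=0.05, seed=0)
        err = np.abs(post.mean_theta.as_array() - THETA_STAR.as_array()) \
            / THETA_STAR.as_array()
        assert err.max() < 0.25

    def test_all_samples_respect_bounds(self, sc8):
        obs = generate_observation(sc8, THETA_STAR, [ALPHA], noise_sd=0.05,
                                   seed=1)
        post = train_posterior(obs.band_fcs[0], sc8, rounds=1, M=60,
                               noise_sd=0.05, seed=1, annealing_iters=10)
        assert np.all(post.theta_samples > LOWER)
        assert np.all(post.theta_samples < UPPER)

    def test_marginal_density_normalizes(self):
        # with a diagonal covariance the bounded-space density factorizes;
        # each marginal, Jacobian-corrected, must integrate to one over its
        # admissible interval
        post = PosteriorEstimate(
            mean_s=np.array([0.4, -0.1, 0.7]), cov_s=np.diag([0.6, 0.4, 0.3]),
            observation="alpha",
            prior=GaussianPrior(np.zeros(3), np.eye(3)),
            theta_samples=np.tile([0.015, 12.0, 0.5], (10, 1)),
            rounds=1, n_simulations=10)
        for k in range(3):
            lo, hi = LOWER[k], UPPER[k]
            grid = np.linspace(lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo),
                               20_001)
            dens = post.marginal_density_theta(k, grid)
            total = integrate.trapezoid(dens, grid)
            assert total == pytest.approx(1.0, abs=1e-3)

    def test_log_density_theta_includes_jacobian(self):
        post = PosteriorEstimate(
            mean_s=np.zeros(3), cov_s=np.eye(3), observation="alpha",
            prior=GaussianPrior(np.zeros(3), np.eye(3)),
            theta_samples=np.tile([0.015, 12.0, 0.5], (5, 1)),
            rounds=1, n_simulations=5)
        theta = SGMParams(0.012, 10.0, 0.4)
        s = to_unbounded(theta)
        expected = post.log_density_s(s) + log_abs_det_jacobian(s)
        assert post.log_density_theta(theta) == pytest.approx(expected)

    def test_summary_quantile_ordering(self, sc8):
        obs = generate_observation(sc8, THETA_STAR, [ALPHA], noise_sd=0.05,
                                   seed=2)
        post = train_posterior(obs.band_fcs[0], sc8, rounds=1, M=60,
                               noise_sd=0.05, seed=2, annealing_iters=10)
        for stats in post.summary().values():
            assert stats["q05"] <= stats["median"] <= stats["q95"]


class TestFitShared:
    def test_single_band_shared_matches_band_specific(self, sc8):
        obs = generate_observation(sc8, THETA_STAR, [ALPHA], noise_sd=0.02,
                                   seed=3)
        shared = obs.shared  # one block
        prior = GaussianPrior(mean=to_unbounded(THETA_STAR), cov=np.eye(3))
        a = fit_shared(shared, sc8, rounds=1, M=60, noise_sd=0.02, seed=4,
                       prior=prior)
        b = train_posterior(obs.band_fcs[0], sc8, rounds=1, M=60,
                            noise_sd=0.02, seed=4, prior=prior)
        np.testing.assert_allclose(a.mean_s, b.mean_s)

    def test_requires_shared_observation(self, sc8):
        obs = generate_observation(sc8, THETA_STAR, [ALPHA], noise_sd=0.02,
                                   seed=3)
        with pytest.raises(TypeError):
            fit_shared(obs.band_fcs[0], sc8)


class TestPosteriorPredictive:
    def test_training_improves_on_wide_prior_mean(self, sc8):
        # from an uninformative mid-box prior, the trained posterior mean
        # should fit the observation at least as well as the prior mean on
        # >= 9 of 10 seeded recovery runs
        theta_true = SGMParams(0.008, 17.0, 0.8)
        mid = GaussianPrior(mean=np.zeros(3), cov=np.eye(3))
        mid_theta = from_unbounded(np.zeros(3))
        mid_vecs = np.concatenate([
            minmax_vectorize(band_fc(sc8, mid_theta, b)) for b in DEFAULT_BANDS])
        wins = 0
        for k in range(10):
            obs = generate_observation(sc8, theta_true, DEFAULT_BANDS,
                                       noise_sd=0.05, seed=300 + k)
            post = train_posterior(obs.shared, sc8, rounds=2, M=300,
                                   noise_sd=0.05, seed=k, prior=mid)
            obs_vec = np.concatenate([minmax_vectorize(b)
                                      for b in obs.band_fcs])
            post_vec = np.concatenate([
                minmax_vectorize(band_fc(sc8, post.mean_theta, b))
                for b in DEFAULT_BANDS])
            wins += (lin_concordance(post_vec, obs_vec)
                     >= lin_concordance(mid_vecs, obs_vec))
        assert wins >= 9
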