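import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from donormix import (
    ConstrainedGaussianMixture,
    MixtureFitResult,
    fit_constrained_mixture,
    mixture_loglikelihood,
    pool_error_rate,
)
from donormix.exceptions import DonorMixError, InsufficientDataError
from donormix.mixture import MIXTURE_WEIGHTS

from .oracles import constrained_loglik, grid_search


@pytest.fixture(scope="module")
def idealized_fractions():
    """Three clearly separated clusters near 0.001 / 0.011 / 0.021
    (error / OSA / NSA at a true donor fraction of 2%)."""
    rng = np.random.default_rng(42)
    return np.clip(
        np.concatenate(
            [
                0.001 + 0.0003 * rng.standard_normal(10),
                0.011 + 0.0005 * rng.standard_normal(21),
                0.021 + 0.0008 * rng.standard_normal(11),
            ]
        ),
        0,
        1,
    )


class TestFitConstrainedMixture:
    def test_recovers_two_percent_on_idealized_clusters(self, idealized_fractions):
        fit = fit_constrained_mixture(idealized_fractions)
        assert fit.converged
        assert fit.mu_nsa - fit.mu_err == pytest.approx(0.020, abs=0.0015)

    def test_loglik_beats_grid_search_oracle(self, idealized_fractions):
        fit = fit_constrained_mixture(idealized_fractions)
        oracle_ll, _ = grid_search(
            idealized_fractions,
            np.linspace(0.0005, 0.002, 16),
            np.linspace(0.008, 0.013, 21),
            np.geomspace(1e-5, 0.002, 16),
            np.geomspace(1e-4, 0.002, 16),
        )
        assert fit.loglik >= oracle_ll - 1e-3

    def test_constant_data_hits_variance_floor_and_matches_oracle(self):
        """All fractions identical at 0.001: sigmas collapse to the floor
        and the ML solution piles the error and OSA components on the
        data (grid-verified), leaving a residual estimate of ~0.1%."""
        x = np.full(12, 0.001)
        fit = fit_constrained_mixture(x)
        assert fit.sigma_err == pytest.approx(1e-5)
        assert fit.sigma_osa == pytest.approx(1e-5)
        oracle_ll, oracle_params = grid_search(
            x,
            np.linspace(0.0, 0.002, 21),
            np.linspace(0.0, 0.002, 21),
            np.geomspace(1e-5, 1e-3, 10),
            np.geomspace(1e-5, 1e-3, 10),
        )
        assert fit.loglik >= oracle_ll - 1e-3
        # grid maximizer: mu_err = mu_osa = 0.001 exactly
        assert oracle_params[0] == pytest.approx(0.001)
        assert oracle_params[1] == pytest.approx(0.001)
        assert fit.donor_fraction == pytest.approx(0.001, abs=1e-4)

    def test_fewer_than_six_fractions_refused(self):
        with pytest.raises(InsufficientDataError):
            fit_constrained_mixture([0.01] * 5)

    def test_non_finite_input_rejected(self):
        with pytest.raises(DonorMixError):
            fit_constrained_mixture([0.01, np.nan, 0.02, 0.01, 0.02, 0.01])

    def test_loglik_monotone_and_constraints_exact(self, rng):
        """EM ascent and the 1:2 mean/SD ties on 100 random inputs."""
        for _ in range(100):
            n = rng.integers(6, 60)
            x = np.clip(rng.gamma(2.0, 0.005, size=n), 0, 1)
            fit = fit_constrained_mixture(x)
            path = np.asarray(fit.loglik_path)
            assert np.all(np.diff(path) >= -1e-9)
            assert fit.mu_nsa == 2.0 * fit.mu_osa
            assert fit.sigma_nsa == 2.0 * fit.sigma_osa

    def test_em_at_least_grid_on_random_small_inputs(self, rng):
        """EM (best of a few deterministic-anchored starts) attains the
        grid-search optimum on small inputs."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = np.clip(
                np.concatenate(
                    [
                        0.0005 + 0.0004 * r.standard_normal(8),
                        0.008 + 0.002 * r.standard_normal(12),
                        0.016 + 0.003 * r.standard_normal(8),
                    ]
                ),
                0,
                1,
            )
            fit = fit_constrained_mixture(x)
            med = float(np.median(x))
            oracle_ll, _ = grid_search(
                x,
                np.linspace(0.0, 0.002, 11),
                np.linspace(0.25 * med, 1.5 * med, 26),
                np.geomspace(1e-5, 0.004, 12),
                np.geomspace(1e-4, 0.006, 12),
            )
            assert fit.loglik >= oracle_ll - 1e-3


class TestMixtureLoglikelihood:
    def params(self, mu_err=0.001, mu_osa=0.01, sigma_err=0.0005, sigma_osa=0.002):
        return MixtureFitResult(
            mu_err=mu_err, mu_osa=mu_osa, mu_nsa=2 * mu_osa,
            sigma_err=sigma_err, sigma_osa=sigma_osa, sigma_nsa=2 * sigma_osa,
        )

    def test_matches_independent_density_summation(self, rng):
        x = np.clip(rng.gamma(2.0, 0.004, size=20), 0, 1)
        p = self.params()
        expected = constrained_loglik(x, p.mu_err, p.mu_osa, p.sigma_err, p.sigma_osa)
        assert mixture_loglikelihood(x, p) == pytest.approx(expected, rel=1e-12)

    def test_single_point_dominated_by_error_component(self):
        """With OSA/NSA means far away, the mixture density at mu_err is
        w1 * N(mu_err; mu_err, sigma_err) in closed form."""
        p = self.params(mu_err=0.001, mu_osa=0.4, sigma_err=0.0005, sigma_osa=0.001)
        expected = np.log(MIXTURE_WEIGHTS[0] / (np.sqrt(2 * np.pi) * p.sigma_err))
        assert mixture_loglikelihood([0.001], p) == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.permutations(list(range(12))))
    def test_invariant_under_permutation(self, perm):
        x = np.linspace(0.0, 0.03, 12)
        p = self.params()
        assert mixture_loglikelihood(x[perm], p) == pytest.approx(
            mixture_loglikelihood(x, p), rel=1e-12
        )

    def test_sigma_below_floor_rejected(self):
        p = self.params(sigma_err=1e-7)
        with pytest.raises(DonorMixError, match="floor"):
            mixture_loglikelihood([0.01], p)

    def test_broken_mean_ratio_rejected(self):
        p = MixtureFitResult(0.001, 0.01, 0.025, 0.001, 0.002, 0.004)
        with pytest.raises(DonorMixError, match="mu_nsa"):
            mixture_loglikelihood([0.01], p)


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = ConstrainedGaussianMixture(tol=1e-6, max_iter=100)
        est2 = clone(est).set_params(max_iter=250)
        assert est2.get_params()["max_iter"] == 250
        assert est2.get_params()["tol"] == 1e-6

    def test_fitted_attributes_and_predict(self, idealized_fractions):
        est = ConstrainedGaussianMixture().fit(idealized_fractions.reshape(-1, 1))
        assert est.converged_
        np.testing.assert_allclose(est.weights_, MIXTURE_WEIGHTS)
        assert est.means_[2] == 2 * est.means_[1]
        labels = est.predict(idealized_fractions)
        # clusters were built in order error, OSA, NSA
        assert labels[:10].tolist() == [0] * 10
        assert labels[-11:].tolist() == [2] * 11
        assert est.score_samples(idealized_fractions).shape == (42,)
        proba = est.predict_proba(idealized_fractions)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, rtol=1e-9)


class TestPoolErrorRate:
    def test_weighted_mean(self):
        assert pool_error_rate([0.001, 0.003], [40, 40]) == pytest.approx(0.002)
        assert pool_error_rate([0.004, 0.0], [10, 30]) == pytest.approx(0.001)

    def test_single_sample_identity(self):
        assert pool_error_rate([0.0017], [42]) == pytest.approx(0.0017)

    def test_accepts_fit_results(self):
        p = MixtureFitResult(0.002, 0.01, 0.02, 0.001, 0.002, 0.004)
        assert pool_error_rate([p, 0.004], [10, 10]) == pytest.approx(0.003)

    @pytest.mark.parametrize("fits,counts", [([], []), ([0.001], [0]), ([0.001], [1, 2])])
    def test_invalid_inputs_rejected(self, fits, counts):
        with pytest.raises(DonorMixError):
            pool_error_rate(fits, counts)
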