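"""Gradient-matching joint density against dense Gaussian oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import fgpgm
from fgpgm.density import DensityConfig, JointDensity
from fgpgm.systems import system_from_config


@pytest.fixture(scope="module")
def lv_setup():
    lv = fgpgm.registry_get("lotka_volterra")
    scheme = fgpgm.ObservationScheme.from_names(lv, ["x1"], ["x2"])
    t = np.linspace(0, 2, 5)
    data = fgpgm.generate_dataset(lv, (2, 1, 4, 1), (5, 3), t,
                                  fgpgm.NoiseSpec(sd=0.1), scheme, seed=3)
    kern = fgpgm.Kernel("rbf", {"variance": 2.0, "lengthscale": 0.6})
    gp = fgpgm.build_gp_matrices(kern, t, center=float(data.values[:, 0].mean()),
                                 noise_sd=0.1)
    rng = np.random.default_rng(2)
    x_M = data.values[:, 0] + 0.05 * rng.standard_normal(5)
    latent = fgpgm.integrate(lv, (2, 1, 4, 1), (x_M[0], 3.0), t)[:, 1]
    return lv, t, data, gp, x_M, latent


class TestObservedDensity:
    def test_matches_sum_of_dense_gaussian_logpdfs(self, lv_setup):
        lv, t, data, gp, x_M, latent = lv_setup
        theta = np.array([2.0, 1.0, 4.0, 1.0])
        cfg = DensityConfig(gamma=0.3)
        val = fgpgm.log_density_observed({0: gp}, lv, x_M, theta,
                                         data.values[:, 0], cfg, latent=latent)
        n = t.size
        Cj = gp.C + gp.jitter * np.eye(n)
        F = lv.rhs(np.column_stack([x_M, latent]), theta, t)
        expected = (
            multivariate_normal.logpdf(x_M - gp.mean, np.zeros(n), Cj)
            + multivariate_normal.logpdf(data.values[:, 0], x_M, 0.01 * np.eye(n))
            + multivariate_normal.logpdf(
                F[:, 0], gp.Dmat @ (x_M - gp.mean), gp.A + 0.09 * np.eye(n)
            )
        )
        assert val == pytest.approx(expected, abs=1e-9)

    def test_out_of_domain_theta_is_minus_inf(self, lv_setup):
        lv, t, data, gp, x_M, latent = lv_setup
        val = fgpgm.log_density_observed(
            {0: gp}, lv, x_M, np.array([-1.0, 1, 4, 1]), data.values[:, 0],
            DensityConfig(gamma=0.3), latent=latent,
        )
        assert val == -np.inf

    def test_gamma_zero_allowed_only_with_spd_mismatch_covariance(self, lv_setup):
        lv, t, data, gp, x_M, latent = lv_setup
        # here A is strictly positive definite: gamma = 0 is a legal limit
        val = fgpgm.log_density_observed({0: gp}, lv, x_M,
                                         np.array([2.0, 1, 4, 1]),
                                         data.values[:, 0],
                                         DensityConfig(gamma=0.0), latent=latent)
        assert np.isfinite(val)
        # on a dense grid with a long lengthscale A degenerates, and
        # gamma = 0 must surface as a conditioning error, not silent noise
        from fgpgm.density import JointDensity
        dense_t = np.linspace(0, 2, 30)
        gpd = fgpgm.build_gp_matrices(
            fgpgm.Kernel("rbf", {"variance": 2.0, "lengthscale": 2.0}), dense_t
        )
        with pytest.raises(np.linalg.LinAlgError):
            JointDensity(lv, dense_t, {0: gpd}, {0: np.zeros(30)},
                         DensityConfig(gamma=0.0))

    def test_gamma_config_validation(self):
        with pytest.raises(ValueError):
            DensityConfig(gamma=-0.1)


class TestLatentDensity:
    def test_matches_dense_oracle(self, lv_setup):
        lv, t, data, gp, x_M, latent = lv_setup
        gpl = fgpgm.build_gp_matrices(
            fgpgm.Kernel("rbf", {"variance": 2.0, "lengthscale": 0.6}), t,
            center=float(latent.mean()),
        )
        theta = np.array([2.0, 1.0, 4.0, 1.0])
        val = fgpgm.log_density_latent({1: gpl}, lv, x_M, latent, theta,
                                       DensityConfig(gamma=0.3))
        n = t.size
        F = lv.rhs(np.column_stack([x_M, latent]), theta, t)
        expected = multivariate_normal.logpdf(
            latent - gpl.mean, np.zeros(n), gpl.C + gpl.jitter * np.eye(n)
        ) + multivariate_normal.logpdf(
            F[:, 1], gpl.Dmat @ (latent - gpl.mean), gpl.A + 0.09 * np.eye(n)
        )
        assert val == pytest.approx(expected, abs=1e-9)

    def test_independent_of_observations(self, lv_setup):
        # the latent term has no data-attachment factor at all
        lv, t, data, gp, x_M, latent = lv_setup
        gpl = fgpgm.build_gp_matrices(
            fgpgm.Kernel("rbf", {"variance": 1.0, "lengthscale": 0.5}), t,
            center=0.0,
        )
        theta = np.array([2.0, 1.0, 4.0, 1.0])
        a = fgpgm.log_density_latent({1: gpl}, lv, x_M, latent, theta,
                                     DensityConfig(gamma=0.3))
        b = fgpgm.log_density_latent({1: gpl}, lv, x_M + 123.0, latent, theta,
                                     DensityConfig(gamma=0.3))
        # x_M enters only through f; perturbing y (not x_M) is impossible by
        # construction, so check bit-identity under a fresh evaluation
        assert a == fgpgm.log_density_latent({1: gpl}, lv, x_M, latent, theta,
                                             DensityConfig(gamma=0.3))
        assert a != b  # sanity: it does depend on the states themselves

    def test_zero_residual_attains_normalizer_maximum(self):
        # a frozen system (f == 0) with the latent path at the GP mean makes
        # both residuals exactly zero: the density equals the two Gaussian
        # normalizers' maxima summed
        sy = system_from_config({
            "name": "frozen", "states": ["u", "v"], "params": ["k"],
            "rhs": {"u": "0*u", "v": "0*v"},
        })
        t = np.linspace(0, 1, 4)
        kern = fgpgm.Kernel("rbf", {"variance": 1.5, "lengthscale": 0.7})
        gpl = fgpgm.build_gp_matrices(kern, t, center=2.5)
        x_L = np.full(4, 2.5)
        val = fgpgm.log_density_latent({1: gpl}, sy, np.zeros(4), x_L,
                                       np.array([1.0]), DensityConfig(gamma=0.2))
        n = 4
        Cj = gpl.C + gpl.jitter * np.eye(n)
        expected = (
            -0.5 * np.log(np.linalg.det(Cj)) - n / 2 * np.log(2 * np.pi)
            - 0.5 * np.log(np.linalg.det(gpl.A + 0.04 * np.eye(n)))
            - n / 2 * np.log(2 * np.pi)
        )
        assert val == pytest.approx(expected, abs=1e-9)

    def test_zero_residual_value_increases_as_gamma_shrinks(self):
        sy = system_from_config({
            "name": "frozen", "states": ["u"], "params": ["k"],
            "rhs": {"u": "0*u"},
        })
        t = np.linspace(0, 1, 4)
        gpl = fgpgm.build_gp_matrices(
            fgpgm.Kernel("rbf", {"variance": 1.0, "lengthscale": 0.5}), t,
            center=0.0,
        )
        vals = [
            fgpgm.log_density_latent({0: gpl}, sy, np.zeros((4, 0)), np.zeros(4),
                                     np.array([1.0]), DensityConfig(gamma=g))
            for g in (0.4, 0.2, 0.1)
        ]
        assert vals[0] < vals[1] < vals[2]


class TestDecomposition:
    def test_full_density_is_observed_plus_latent(self, lv_setup):
        lv, t, data, gp, x_M, latent = lv_setup
        gpl = fgpgm.build_gp_matrices(
            fgpgm.Kernel("rbf", {"variance": 2.0, "lengthscale": 0.6}), t,
            center=float(latent.mean()),
        )
        cfg = DensityConfig(gamma=0.3)
        dens = JointDensity(lv, t, {0: gp}, {0: data.values[:, 0]}, cfg,
                            gp_latent={1: gpl})
        X = np.column_stack([x_M, latent])
        theta = np.array([2.0, 1.0, 4.0, 1.0])
        total = dens.full_logp(X, theta)
        assert total == dens.observed_logp(X, theta) + dens.latent_logp(X, theta)
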