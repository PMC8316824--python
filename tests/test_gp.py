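"""GP kernels, derivative cross-covariances, marginal likelihood, fitting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fgpgm
from fgpgm.gp import ConditioningError, _kernel_all, kernel_matrices

KERNELS = {
    "rbf": {"variance": 1.3, "lengthscale": 0.7},
    "matern52": {"variance": 0.9, "lengthscale": 0.5},
    "sigmoid": {"a": 1.1, "b": 0.4, "c": 0.15},
}


def make_kernel(family):
    return fgpgm.Kernel(family, dict(KERNELS[family]))


class TestKernelEval:
    def test_rbf_zero_lag_is_variance(self):
        k = make_kernel("rbf")
        assert fgpgm.kernel_eval(k, 1.3, 1.3) == pytest.approx(1.3)

    @given(t1=st.floats(-5, 5), t2=st.floats(-5, 5),
           family=st.sampled_from(sorted(KERNELS)))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry(self, t1, t2, family):
        k = make_kernel(family)
        assert fgpgm.kernel_eval(k, t1, t2) == pytest.approx(
            fgpgm.kernel_eval(k, t2, t1), rel=1e-12, abs=1e-12
        )

    def test_matern52_closed_form_at_one_lengthscale(self):
        # independent evaluation of v(1 + √5 + 5/3)exp(−√5) at lag = l
        v, l = 0.9, 0.5
        k = fgpgm.Kernel("matern52", {"variance": v, "lengthscale": l})
        s5 = np.sqrt(5.0)
        expected = v * (1 + s5 + 5.0 / 3.0) * np.exp(-s5)
        assert fgpgm.kernel_eval(k, 0.0, l) == pytest.approx(expected, rel=1e-12)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            fgpgm.Kernel("rbf", {"variance": -1.0, "lengthscale": 0.5})
        with pytest.raises(ValueError):
            fgpgm.Kernel("rbf", {"variance": np.nan, "lengthscale": 0.5})
        with pytest.raises(ValueError):
            fgpgm.Kernel("brownian", {})

    @pytest.mark.parametrize("family", sorted(KERNELS))
    def test_gram_matrix_positive_semidefinite(self, family):
        rng = np.random.default_rng(0)
        for _ in range(5):
            t = np.sort(rng.uniform(0, 10, size=12))
            C, _, _ = kernel_matrices(make_kernel(family), t)
            eigs = np.linalg.eigvalsh(C)
            assert eigs.min() >= -1e-8 * np.trace(C)


class TestDerivativeCrossCovariances:
    @pytest.mark.parametrize("family", sorted(KERNELS))
    def test_analytic_derivatives_match_finite_differences(self, family):
        k = make_kernel(family)
        t = np.array([0.3, 1.1, 2.7, 4.0])
        T1, T2 = t[:, None], t[None, :]
        _, C1, C12 = kernel_matrices(k, t)
        h = 1e-5
        k1_fd = (_kernel_all(k, T1 + h, T2)[0] - _kernel_all(k, T1 - h, T2)[0]) / (2 * h)
        k12_fd = (
            _kernel_all(k, T1 + h, T2 + h)[0]
            - _kernel_all(k, T1 + h, T2 - h)[0]
            - _kernel_all(k, T1 - h, T2 + h)[0]
            + _kernel_all(k, T1 - h, T2 - h)[0]
        ) / (4 * h * h)
        scale = np.max(np.abs(k1_fd)) + 1e-12
        assert np.max(np.abs(C1 - k1_fd)) / scale < 1e-4
        scale2 = np.max(np.abs(k12_fd)) + 1e-12
        assert np.max(np.abs(C12 - k12_fd)) / scale2 < 1e-4


class TestBuildGPMatrices:
    def test_single_point_derivative_mean_is_zero(self):
        for family in ("rbf", "matern52"):
            gp = fgpgm.build_gp_matrices(make_kernel(family), [1.7])
            np.testing.assert_allclose(gp.Dmat, [[0.0]], atol=1e-12)

    def test_conditional_identity_holds_by_construction(self):
        k = make_kernel("rbf")
        t = np.linspace(0, 3, 8)
        gp = fgpgm.build_gp_matrices(k, t)
        C, C1, C12 = kernel_matrices(k, t)
        Cinv = np.linalg.inv(C + gp.jitter * np.eye(t.size))
        np.testing.assert_allclose(gp.A, C12 - C1 @ Cinv @ C1.T, atol=1e-10)
        np.testing.assert_allclose(gp.Dmat, C1 @ Cinv, atol=1e-10)

    def test_dmat_matches_dense_joint_conditioning(self):
        # brute-force conditioning on the stacked (x, dx) joint Gaussian
        k = make_kernel("rbf")
        t = np.linspace(0, 2, 6)
        gp = fgpgm.build_gp_matrices(k, t)
        C, C1, C12 = kernel_matrices(k, t)
        n = t.size
        joint = np.block([[C + gp.jitter * np.eye(n), C1.T], [C1, C12]])
        rng = np.random.default_rng(1)
        x = np.linalg.cholesky(joint[:n, :n]) @ rng.standard_normal(n)
        cond_mean = joint[n:, :n] @ np.linalg.inv(joint[:n, :n]) @ x
        np.testing.assert_allclose(gp.Dmat @ x, cond_mean, atol=1e-10)

    def test_a_matches_monte_carlo_derivative_covariance(self):
        # empirical covariance blocks from 50,000 dense-grid GP draws,
        # derivatives by central differences on the dense grid
        k = fgpgm.Kernel("rbf", {"variance": 1.0, "lengthscale": 0.8})
        coarse = np.linspace(0.2, 1.8, 5)
        dense = np.linspace(0, 2, 401)
        h = dense[1] - dense[0]
        Cd, _, _ = kernel_matrices(k, dense)
        L = np.linalg.cholesky(Cd + 1e-10 * np.eye(dense.size))
        rng = np.random.default_rng(2)
        draws = (L @ rng.standard_normal((dense.size, 50_000))).T
        idx = np.searchsorted(dense, coarse)
        x = draws[:, idx]
        dx = (draws[:, idx + 1] - draws[:, idx - 1]) / (2 * h)
        big = np.cov(np.hstack([x, dx]).T)
        Sxx, Sdx = big[:5, :5], big[5:, :5]
        Sdd = big[5:, 5:]
        A_emp = Sdd - Sdx @ np.linalg.inv(Sxx) @ Sdx.T
        gp = fgpgm.build_gp_matrices(k, coarse)
        # Monte-Carlo + O(h²) finite-difference error budget
        assert np.max(np.abs(A_emp - gp.A)) < 0.02

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fgpgm.build_gp_matrices(make_kernel("rbf"), [0.0, 1.0, 1.0])


class TestLogMarginalLikelihood:
    def test_single_observation_normalizer(self):
        k = fgpgm.Kernel("rbf", {"variance": 2.0, "lengthscale": 1.0})
        # centred single observation is 0; density collapses to the
        # 1-D Gaussian normalizer with variance c + sigma^2
        val = fgpgm.log_marginal_likelihood(k, 0.3, [1.0], [5.0])
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi * (2.0 + 0.09)))

    def test_dense_explicit_inverse_oracle(self):
        k = make_kernel("matern52")
        t = np.linspace(0, 4, 6)
        rng = np.random.default_rng(3)
        y = np.sin(t) + 0.1 * rng.standard_normal(6)
        sigma = 0.23
        C, _, _ = kernel_matrices(k, t)
        K = C + sigma**2 * np.eye(6)
        yc = y - y.mean()
        expected = (
            -0.5 * yc @ np.linalg.inv(K) @ yc
            - 0.5 * np.log(np.linalg.det(K))
            - 3 * np.log(2 * np.pi)
        )
        assert fgpgm.log_marginal_likelihood(k, sigma, t, y) == pytest.approx(
            expected, abs=1e-10
        )

    def test_scaling_y_strictly_decreases_value(self):
        k = make_kernel("rbf")
        t = np.linspace(0, 2, 8)
        y = np.sin(2 * t)
        a = fgpgm.log_marginal_likelihood(k, 0.1, t, y)
        b = fgpgm.log_marginal_likelihood(k, 0.1, t, 2 * y)
        assert b < a


class TestFitHyperparameters:
    def test_recovers_known_lengthscale(self):
        # data from a known RBF GP; median relative error over replicates
        true = fgpgm.Kernel("rbf", {"variance": 1.0, "lengthscale": 0.5})
        t = np.linspace(0, 5, 100)
        C, _, _ = kernel_matrices(true, t)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(100))
        rng = np.random.default_rng(4)
        rel = []
        for _ in range(20):
            y = L @ rng.standard_normal(100) + 0.1 * rng.standard_normal(100)
            fit = fgpgm.fit_hyperparameters(t, y, "rbf", n_restarts=4, seed=5)
            rel.append(abs(fit.kernel.params["lengthscale"] - 0.5) / 0.5)
        assert np.median(rel) < 0.25

    def test_objective_is_reproducible_from_returned_values(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 2, 20)
        y = np.cos(3 * t) + 0.05 * rng.standard_normal(20)
        fit = fgpgm.fit_hyperparameters(t, y, "rbf", n_restarts=5, seed=0)
        recheck = fgpgm.log_marginal_likelihood(fit.kernel, fit.noise_sd, t, y)
        assert recheck == pytest.approx(fit.log_marginal, abs=1e-9)

    def test_constant_observations_warn_and_degenerate_sigma(self):
        t = np.linspace(0, 1, 10)
        with pytest.warns(RuntimeWarning, match="constant"):
            fit = fgpgm.fit_hyperparameters(t, np.full(10, 2.0), "rbf",
                                            n_restarts=3, seed=0)
        assert fit.noise_sd < 1e-2

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fgpgm.fit_hyperparameters([0, 1, 2], [1, 2, 3], "rbf")

    def test_nested_grid_per_point_likelihood_sanity(self):
        # extending the grid by one point cannot shift the maximized
        # per-point marginal likelihood by more than a single-point
        # normalizer's worth (loose sanity bound)
        rng = np.random.default_rng(8)
        t11 = np.linspace(0, 2, 11)
        y11 = np.sin(3 * t11) + 0.05 * rng.standard_normal(11)
        f10 = fgpgm.fit_hyperparameters(t11[:10], y11[:10], "rbf",
                                        n_restarts=4, seed=0)
        f11 = fgpgm.fit_hyperparameters(t11, y11, "rbf", n_restarts=4, seed=0)
        per10 = f10.log_marginal / 10
        per11 = f11.log_marginal / 11
        c = f11.kernel.params["variance"] + f11.noise_sd**2
        bound = abs(-0.5 * np.log(2 * np.pi * c)) + 1.0
        assert abs(per11 - per10) < bound

    def test_serialization_block(self):
        gp = fgpgm.build_gp_matrices(make_kernel("rbf"), np.linspace(0, 1, 5),
                                     center=0.3, noise_sd=0.1)
        text = gp.to_text()
        assert "family: rbf" in text and "grid_sha256" in text
        assert "noise_sd: 0.1" in text
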