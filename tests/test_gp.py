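"""Gaussian process core: kernel closed forms, dense-algebra oracles,
marginal likelihood, MAP fitting and PSD/variance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fertgp.gp as gp
from fertgp.gp import (GammaPrior, GPModel, KernelHyperparams,
                       SES_LENGTHSCALE_PRIOR, fit_gp, gp_log_marginal,
                       gp_posterior, kernel_matrix, sqexp_kernel)


def _h(sf=1.0, sn=0.1, ls=(1.0,)):
    return KernelHyperparams(signal_variance=sf, noise_variance=sn,
                             lengthscales=np.asarray(ls, float))


class TestKernel:
    def test_same_point_with_and_without_noise(self):
        h = _h(sf=2.0, sn=0.5)
        assert sqexp_kernel([1.0], [1.0], h, same_index=True) == pytest.approx(2.5)
        assert sqexp_kernel([1.0], [1.0], h, same_index=False) == pytest.approx(2.0)

    def test_unit_separation_closed_form(self):
        h = _h(sf=1.0, sn=0.3)
        assert sqexp_kernel([0.0], [1.0], h) == pytest.approx(math.exp(-0.5))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            sqexp_kernel([1.0, 2.0], [1.0], _h())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=15),
           st.integers(min_value=1, max_value=3),
           st.integers(min_value=0, max_value=10**6))
    def test_gram_matrix_is_symmetric_psd(self, n, d, raw_seed):
        rng = np.random.default_rng(raw_seed)
        X = rng.normal(size=(n, d)) * 3
        h = _h(sf=float(rng.uniform(0.1, 5)), sn=float(rng.uniform(0, 1)),
               ls=rng.uniform(0.2, 5, size=d))
        K = kernel_matrix(X, X, h, noise_diag=True)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestPosterior:
    def test_noiseless_interpolation(self, rng):
        X = rng.uniform(0, 5, size=(8, 2))
        y = np.sin(X[:, 0]) + X[:, 1]
        h = _h(sf=2.0, sn=0.0, ls=(1.5, 1.5))
        post = gp_posterior(X, X, y, h)
        assert np.max(np.abs(post.mean - y)) < 1e-6
        assert np.max(post.variance) < 1e-6

    def test_single_point_closed_form(self):
        h = _h(sf=1.5, sn=0.4)
        X, y = np.array([[0.0]]), np.array([2.0])
        xq = np.array([[0.7]])
        post = gp_posterior(xq, X, y, h)
        k = 1.5 * math.exp(-0.5 * 0.49)
        assert post.mean[0] == pytest.approx(k * 2.0 / (1.5 + 0.4))

    def test_matches_dense_inverse_oracle(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        Xq = rng.normal(size=(4, 2))
        h = _h(sf=1.3, sn=0.2, ls=(0.8, 1.7))
        post = gp_posterior(Xq, X, y, h)
        # brute force with explicit inverse
        K = kernel_matrix(X, X, h, noise_diag=True)
        Ks = kernel_matrix(Xq, X, h)
        Kss = kernel_matrix(Xq, Xq, h)
        Kinv = np.linalg.inv(K)
        mu = Ks @ Kinv @ y
        cov = Kss - Ks @ Kinv @ Ks.T
        assert np.max(np.abs(post.mean - mu)) < 1e-8
        assert np.max(np.abs(post.cov - cov)) < 1e-8

    def test_posterior_variance_bounded_by_prior(self, rng):
        X = rng.normal(size=(12, 1))
        y = rng.normal(size=12)
        h = _h(sf=2.2, sn=0.3)
        post = gp_posterior(rng.normal(size=(30, 1)) * 3, X, y, h)
        assert np.all(post.variance <= 2.2 + 0.3 + 1e-9)


class TestLogMarginal:
    def test_scalar_closed_form(self):
        h = _h(sf=1.2, sn=0.3)
        y = np.array([0.7])
        v = 1.2 + 0.3
        expect = -0.5 * 0.49 / v - 0.5 * math.log(2 * math.pi * v)
        assert gp_log_marginal(np.array([[0.0]]), y, h) == pytest.approx(expect)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        h = _h(sf=1.0, sn=0.2, ls=(1.0, 2.0))
        perm = rng.permutation(6)
        assert gp_log_marginal(X, y, h) == pytest.approx(
            gp_log_marginal(X[perm], y[perm], h), abs=1e-9)

    def test_matches_dense_determinant_oracle(self, rng):
        X = rng.normal(size=(3, 1))
        y = rng.normal(size=3)
        h = _h(sf=0.9, sn=0.5)
        K = kernel_matrix(X, X, h, noise_diag=True)
        expect = (-0.5 * y @ np.linalg.inv(K) @ y
                  - 0.5 * math.log(np.linalg.det(K))
                  - 1.5 * math.log(2 * math.pi))
        assert gp_log_marginal(X, y, h) == pytest.approx(expect, abs=1e-8)

    def test_prior_term_added(self):
        h = _h(sf=1.0, sn=0.1, ls=(1.25,))
        X, y = np.array([[0.0], [1.0], [2.0]]), np.array([0.1, -0.2, 0.3])
        base = gp_log_marginal(X, y, h)
        with_prior = gp_log_marginal(X, y, h, {0: SES_LENGTHSCALE_PRIOR})
        assert with_prior == pytest.approx(
            base + SES_LENGTHSCALE_PRIOR.logpdf(1.25))


class TestFit:
    def test_constant_targets_give_flat_mean_small_signal(self, rng):
        X = rng.uniform(0, 4, size=(20, 1))
        y = np.full(20, 3.7)
        model = fit_gp(X, y, seed=0, n_restarts=4)
        pred = model.predict(np.linspace(0, 4, 9)[:, None])
        assert np.allclose(pred, 3.7, atol=1e-3)
        assert model.hyperparams.signal_variance < 0.1

    def test_lengthscale_recovery_within_factor_two(self, rng):
        X = np.sort(rng.uniform(0, 10, size=(100, 1)), axis=0)
        true_h = _h(sf=1.0, sn=0.01, ls=(1.0,))
        K = kernel_matrix(X, X, true_h, noise_diag=True)
        y = np.linalg.cholesky(K) @ rng.standard_normal(100)
        model = fit_gp(X, y, seed=3, n_restarts=6)
        fitted = float(model.hyperparams.lengthscales[0])
        assert 0.5 <= fitted <= 2.0

    def test_prior_dominates_uninformative_data(self):
        """With three zero targets, the SES lengthscale sits at the prior
        mode (shape-1)*scale = 1.25."""
        X = np.array([[1.0], [2.5], [4.0]])
        y = np.zeros(3)
        model = fit_gp(X, y, priors={0: SES_LENGTHSCALE_PRIOR}, seed=0,
                       n_restarts=6)
        assert float(model.hyperparams.lengthscales[0]) == pytest.approx(1.25, rel=0.4)

    def test_map_objective_not_worse_than_data_driven_start(self, rng):
        X = rng.uniform(0, 5, size=(25, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(25)
        model = fit_gp(X, y, seed=1, n_restarts=5, mean="zero")
        start = KernelHyperparams(
            signal_variance=max(float(np.mean(y * y)), 1e-10),
            noise_variance=max(float(np.mean(y * y)), 1e-10) * math.exp(-2.0),
            lengthscales=np.ptp(X, axis=0))
        assert (gp_log_marginal(X, y, model.hyperparams)
                >= gp_log_marginal(X, y, start) - 1e-6)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_gp(np.array([[0.0], [1.0]]), np.array([1.0, 2.0]))

    def test_jitter_handles_duplicate_inputs(self):
        X = np.array([[1.0], [1.0], [2.0]])
        y = np.array([0.5, 0.5, 1.0])
        h = _h(sf=1.0, sn=0.0)
        model = GPModel(X=X, y=y, hyperparams=h, mean_offset=0.0)
        assert np.isfinite(model.predict(np.array([[1.5]]))).all()
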