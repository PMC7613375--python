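"""Tests of the ARD Rational Quadratic GP: kernel algebra, evidence and its
gradient, exact posterior recovery, and band relevance."""

import numpy as np
import pytest

from hytrait import gpr
from hytrait.errors import ValidationError


def _theta(l2, sf2=1.0, alpha=1.0, sn2=0.0):
    return gpr.GPRHyperparams(sf2, alpha, np.asarray(l2, float), sn2)


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        th = _theta([1.0, 2.0], sf2=2.7)
        x = np.array([[0.3, -1.2]])
        assert gpr.kernel_matrix(x, x, th)[0, 0] == pytest.approx(2.7)

    def test_direct_scalar_evaluation(self):
        # B=1, sf2=1, alpha=1, l=1, |d|=sqrt(2) -> (1 + 2/2)^-1 = 0.5
        th = _theta([1.0])
        k = gpr.kernel_matrix([[0.0]], [[np.sqrt(2.0)]], th)
        assert k[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_large_alpha_recovers_squared_exponential(self, rng):
        X = rng.normal(size=(15, 3))
        l2 = np.array([0.5, 1.0, 2.0])
        th = _theta(l2, alpha=1e6)
        K = gpr.kernel_matrix(X, X, th)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2 / l2).sum(-1)
        assert np.abs(K - np.exp(-0.5 * d2)).max() < 1e-4

    def test_symmetry_and_psd(self, rng):
        X = rng.normal(size=(25, 4))
        th = _theta(rng.random(4) + 0.2, sf2=1.4, alpha=0.7)
        K = gpr.kernel_matrix(X, X, th)
        assert np.allclose(K, K.T)
        evals = np.linalg.eigvalsh(K)
        assert evals.min() > -1e-10

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            gpr.kernel_matrix(np.zeros((2, 3)), np.zeros((2, 3)), _theta([1.0]))


class TestEvidence:
    def test_single_point_closed_form(self):
        # N=1, y=0: lml = -1/2 log(2 pi (sf2 + sn2)).
        th = _theta([1.0], sf2=1.3, sn2=0.2)
        lml = gpr.log_marginal_likelihood(np.zeros((1, 1)), np.zeros(1), th)
        assert lml == pytest.approx(-0.5 * np.log(2 * np.pi * 1.5), abs=1e-12)

    def test_matches_dense_gaussian_density(self, rng):
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        th = _theta([0.7, 1.5], sf2=2.0, alpha=1.3, sn2=0.1)
        K = gpr.kernel_matrix(X, X, th) + 0.1 * np.eye(12)
        sign, logdet = np.linalg.slogdet(K)
        expected = -0.5 * y @ np.linalg.solve(K, y) - 0.5 * logdet - 6 * np.log(2 * np.pi)
        assert gpr.log_marginal_likelihood(X, y, th) == pytest.approx(expected, rel=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        th = _theta([0.8, 1.2, 2.0], sf2=1.5, alpha=0.9, sn2=0.05)
        _, g = gpr.log_marginal_likelihood(X, y, th, with_grad=True)
        v = th.to_vector()
        for i in range(v.size):
            e = np.zeros_like(v)
            e[i] = 1e-6
            fd = (gpr.log_marginal_likelihood(X, y, gpr.GPRHyperparams.from_vector(v + e))
                  - gpr.log_marginal_likelihood(X, y, gpr.GPRHyperparams.from_vector(v - e))) / 2e-6
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestPosterior:
    def test_exact_against_dense_solve_small_n(self, rng):
        # Exact agreement with brute-force linear algebra on all N <= 10.
        for n in range(2, 11):
            X = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            th = _theta(rng.random(3) + 0.3, sf2=1.2, alpha=1.1, sn2=0.05)
            model = gpr.GPRModel(X=X, y_centered=y, theta=th,
                                 x_mean=np.zeros(3), x_scale=np.ones(3), y_mean=0.0)
            Xs = rng.normal(size=(4, 3))
            Ky = gpr.kernel_matrix(X, X, th) + th.noise_var * np.eye(n)
            ks = gpr.kernel_matrix(Xs, X, th)
            mu = ks @ np.linalg.solve(Ky, y)
            var = th.signal_var - np.einsum("mn,nm->m", ks, np.linalg.solve(Ky, ks.T))
            p = gpr.predict(model, Xs)
            np.testing.assert_allclose(p.mean, mu, atol=1e-10)
            np.testing.assert_allclose(p.variance, np.clip(var, 0, None), atol=1e-10)

    def test_noiseless_interpolation_at_training_points(self, rng):
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        th = _theta([1.0, 1.0], sn2=0.0)
        model = gpr.GPRModel(X=X, y_centered=y, theta=th,
                             x_mean=np.zeros(2), x_scale=np.ones(2), y_mean=0.0)
        p = gpr.predict(model, X)
        np.testing.assert_allclose(p.mean, y, atol=1e-8)
        assert np.all(p.variance <= 1e-8 * th.signal_var)

    def test_prior_reversion_far_from_data(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6) + 5.0
        model = gpr.fit(X, y, restarts=1, seed=0)
        far = np.full((1, 2), 1e6)
        p = gpr.predict(model, far)
        assert p.mean[0] == pytest.approx(model.y_mean, abs=0.3)
        assert p.variance[0] == pytest.approx(model.theta.signal_var, rel=0.01)

    def test_variance_bounded_by_prior_when_noiseless(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        th = _theta([1.0, 2.0], sf2=1.7, sn2=0.0)
        model = gpr.GPRModel(X=X, y_centered=y, theta=th,
                             x_mean=np.zeros(2), x_scale=np.ones(2), y_mean=0.0)
        p = gpr.predict(model, rng.normal(size=(20, 2)))
        assert np.all(p.variance <= th.signal_var + 1e-10)


class TestFit:
    def test_evidence_improves_over_initialization(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=40)
        Xs = (X - X.mean(0)) / X.std(0)
        init = gpr.GPRHyperparams(np.var(y), 1.0, np.ones(2), 0.01 * np.var(y))
        lml0 = gpr.log_marginal_likelihood(Xs, y - y.mean(), init)
        model = gpr.fit(X, y, init=init, restarts=2, seed=0)
        assert model.lml >= lml0 - 1e-9

    def test_constant_targets_predict_constant(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.full(10, 3.3)
        model = gpr.fit(X, y, restarts=1, seed=0)
        p = gpr.predict(model, rng.normal(size=(5, 2)))
        np.testing.assert_allclose(p.mean, 3.3, atol=1e-6)

    def test_duplicated_row_stable(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.sin(X[:, 0]) + 0.05 * rng.normal(size=20)
        m0 = gpr.fit(X, y, restarts=1, seed=1)
        Xd = np.vstack([X, X[:1]])
        yd = np.append(y, y[0])
        md = gpr.fit(Xd, yd, init=m0.theta, restarts=1, seed=1)
        q = rng.normal(size=(6, 2))
        assert np.abs(gpr.predict(md, q).mean - gpr.predict(m0, q).mean).max() < 0.05

    def test_lengthscale_ordering_recovery(self):
        # Data from a known anisotropic function: the active dimension should
        # get the smallest fitted lengthscale in >= 9/10 seeded replicates.
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(150, 3))
            y = np.sin(2.0 * X[:, 0]) + 0.05 * rng.normal(size=150)
            model = gpr.fit(X, y, restarts=2, seed=seed)
            if np.argmin(model.theta.lengthscales2) == 0:
                wins += 1
        assert wins >= 9

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            gpr.fit(np.zeros((1, 2)), np.zeros(1))
        with pytest.raises(ValidationError):
            gpr.fit(np.full((3, 2), np.nan), np.zeros(3))


class TestRelevance:
    def _model_with_l2(self, l2):
        n = len(l2)
        return gpr.GPRModel(X=np.zeros((2, n)), y_centered=np.zeros(2),
                            theta=_theta(l2, sn2=1e-6),
                            x_mean=np.zeros(n), x_scale=np.ones(n), y_mean=0.0)

    def test_largest_lengthscale_gets_zero(self):
        r = gpr.band_relevance(self._model_with_l2([1.0, 4.0]))
        assert r[1] == 0.0

    def test_direct_evaluation(self):
        r = gpr.band_relevance(self._model_with_l2([1.0, 4.0]))
        np.testing.assert_allclose(r, [75.0, 0.0])

    def test_equal_lengthscales_all_equal(self):
        r = gpr.band_relevance(self._model_with_l2([2.0, 2.0, 2.0]))
        assert np.all(r == r[0])

    def test_sum_normalized_variant(self):
        r = gpr.band_relevance(self._model_with_l2([1.0, 4.0]), normalize="sum")
        np.testing.assert_allclose(r, [100 * (1 - 1 / 5), 100 * (1 - 4 / 5)])

    def test_single_feature_flagged(self):
        with pytest.warns(UserWarning, match="single-feature"):
            r = gpr.band_relevance(self._model_with_l2([1.0]))
        assert r[0] == 0.0


class TestInvariances:
    def test_feature_permutation_invariance(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        th = _theta([0.5, 1.0, 2.0], sn2=0.05)
        perm = [2, 0, 1]
        th_p = _theta(np.asarray([0.5, 1.0, 2.0])[perm], sn2=0.05)
        m = gpr.GPRModel(X=X, y_centered=y, theta=th, x_mean=np.zeros(3),
                         x_scale=np.ones(3), y_mean=0.0)
        m_p = gpr.GPRModel(X=X[:, perm], y_centered=y, theta=th_p,
                           x_mean=np.zeros(3), x_scale=np.ones(3), y_mean=0.0)
        q = rng.normal(size=(5, 3))
        np.testing.assert_allclose(gpr.predict(m, q).mean,
                                   gpr.predict(m_p, q[:, perm]).mean, atol=1e-12)

    def test_min_eigenvalue_floor(self, rng):
        X = rng.normal(size=(30, 3))
        th = _theta([1.0, 1.0, 1.0], sn2=0.3)
        Ky = gpr.kernel_matrix(X, X, th) + th.noise_var * np.eye(30)
        assert np.linalg.eigvalsh(Ky).min() >= th.noise_var - 1e-10

    def test_serialization_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(12, 2))
        y = np.sin(X[:, 0])
        m = gpr.fit(X, y, restarts=1, seed=0)
        p = tmp_path / "model.json"
        m.save(p)
        back = gpr.GPRModel.load(p)
        q = rng.normal(size=(4, 2))
        np.testing.assert_allclose(gpr.predict(back, q).mean,
                                   gpr.predict(m, q).mean, atol=1e-12)
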