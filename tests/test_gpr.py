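"""GPR engine: kernel closed forms, predictive equations, likelihood,
gradients and training, checked against independent linear-algebra oracles
and scikit-learn."""

import numpy as np
import pytest

from phenolai.gpr import (GaussianProcess, GPRHyperparams, GPRResults,
                          fit_gpr, se_kernel)


def theta1(ls=1.0, s2=1.0, n2=0.0):
    return GPRHyperparams(s2, np.atleast_1d(ls), n2)


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        X = np.array([[1.2, -3.0]])
        th = GPRHyperparams(2.5, [1.0, 4.0], 0.0)
        assert se_kernel(X, X, th)[0, 0] == pytest.approx(2.5)

    def test_unit_distance_1d_closed_form(self):
        K = se_kernel(np.array([[0.0]]), np.array([[1.0]]), theta1())
        assert K[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_matches_elementwise_loop(self, rng):
        Xa = rng.normal(size=(3, 2))
        Xb = rng.normal(size=(5, 2))
        th = GPRHyperparams(1.7, [0.8, 2.3], 0.0)
        K = se_kernel(Xa, Xb, th)
        for i in range(3):
            for j in range(5):
                expo = sum(((Xa[i, b] - Xb[j, b]) / th.lengthscales[b]) ** 2
                           for b in range(2))
                assert K[i, j] == pytest.approx(1.7 * np.exp(-0.5 * expo),
                                                abs=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            se_kernel(np.zeros((2, 3)), np.zeros((2, 3)),
                      GPRHyperparams(1.0, [1.0, 1.0], 0.0))

    def test_symmetry_and_positive_definiteness(self, rng):
        for _ in range(5):
            X = rng.normal(size=(12, 3)) * 5
            th = GPRHyperparams(float(rng.uniform(0.5, 3)),
                                rng.uniform(0.5, 4, 3), 0.01)
            K = se_kernel(X, X, th)
            assert np.allclose(K, K.T, atol=1e-14)
            w = np.linalg.eigvalsh(K + th.sigma_n2 * np.eye(12))
            assert w.min() > 0


class TestPredict:
    def test_interpolates_single_training_point(self):
        res = GPRResults(GaussianProcess([[3.0]], [5.0]), theta1(s2=2.0))
        m, v = res.predict([[3.0]])
        assert m[0] == pytest.approx(5.0, abs=1e-10)
        assert v[0] == pytest.approx(0.0, abs=1e-8)

    def test_reverts_to_prior_far_from_data(self):
        res = GPRResults(GaussianProcess([[0.0], [1.0]], [4.0, 6.0]),
                         theta1(s2=3.0, n2=0.5))
        m, v = res.predict([[1e6]])
        assert m[0] == pytest.approx(5.0, abs=1e-9)      # training mean
        assert v[0] == pytest.approx(3.5, abs=1e-9)      # sigma_s2 + sigma_n2

    def test_two_point_closed_form(self):
        s2, ls, n2 = 2.0, 1.5, 0.1
        x0, x1, y0, y1 = 0.0, 1.0, 1.0, 2.0
        res = GPRResults(GaussianProcess([[x0], [x1]], [y0, y1]),
                         theta1(ls=ls, s2=s2, n2=n2))
        xs = 0.3
        # hand computation on centred targets via 2x2 inverse
        k01 = s2 * np.exp(-0.5 * ((x0 - x1) / ls) ** 2)
        a, b = s2 + n2, k01
        det = a * a - b * b
        Ainv = np.array([[a, -b], [-b, a]]) / det
        ks = np.array([s2 * np.exp(-0.5 * ((xs - x0) / ls) ** 2),
                       s2 * np.exp(-0.5 * ((xs - x1) / ls) ** 2)])
        yc = np.array([y0, y1]) - 1.5
        mean_hand = ks @ Ainv @ yc + 1.5
        var_hand = s2 + n2 - ks @ Ainv @ ks
        m, v = res.predict([[xs]])
        assert m[0] == pytest.approx(mean_hand, abs=1e-10)
        assert v[0] == pytest.approx(var_hand, abs=1e-10)

    def test_matches_dense_inverse_oracle(self, rng):
        for n in (2, 5, 20):
            X = rng.normal(size=(n, 2)) * 3
            y = rng.normal(size=n)
            th = GPRHyperparams(1.3, [1.0, 2.0], 0.05)
            res = GPRResults(GaussianProcess(X, y), th)
            Xs = rng.normal(size=(4, 2)) * 3
            K = se_kernel(X, X, th)
            Ainv = np.linalg.inv(K + th.sigma_n2 * np.eye(n))
            ks = se_kernel(Xs, X, th)
            yc = y - y.mean()
            mean_o = ks @ Ainv @ yc + y.mean()
            var_o = th.sigma_s2 + th.sigma_n2 - np.einsum(
                "ij,jk,ik->i", ks, Ainv, ks)
            m, v = res.predict(Xs)
            np.testing.assert_allclose(m, mean_o, atol=1e-8)
            np.testing.assert_allclose(v, var_o, atol=1e-8)

    def test_invariant_to_training_permutation(self, rng):
        X = rng.normal(size=(15, 1))
        y = rng.normal(size=15)
        th = theta1(ls=0.7, s2=1.2, n2=0.1)
        perm = rng.permutation(15)
        m1, v1 = GPRResults(GaussianProcess(X, y), th).predict([[0.2]])
        m2, v2 = GPRResults(GaussianProcess(X[perm], y[perm]), th).predict([[0.2]])
        assert m1[0] == pytest.approx(m2[0], abs=1e-10)
        assert v1[0] == pytest.approx(v2[0], abs=1e-10)

    def test_variance_never_exceeds_prior(self, rng):
        X = rng.uniform(0, 10, size=(25, 1))
        y = rng.normal(size=25)
        th = theta1(ls=1.0, s2=2.0, n2=0.3)
        res = GPRResults(GaussianProcess(X, y), th)
        _, v = res.predict(rng.uniform(-5, 15, size=(50, 1)))
        assert np.all(v <= th.sigma_s2 + th.sigma_n2 + res.jitter + 1e-12)

    def test_matches_sklearn_fixed_hyperparameters(self, rng):
        sklearn = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        X = rng.uniform(0, 10, size=(20, 1))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=20)
        s2, ls, n2 = 1.5, 2.0, 0.04
        res = GPRResults(GaussianProcess(X, y), theta1(ls=ls, s2=s2, n2=n2))
        yc = y - y.mean()
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(s2, "fixed") * RBF(ls, "fixed"),
            alpha=n2, optimizer=None).fit(X, yc)
        m_sk, sd_sk = gp.predict(np.array([[2.5], [7.1]]), return_std=True)
        m, v = res.predict(np.array([[2.5], [7.1]]))
        np.testing.assert_allclose(m, m_sk + y.mean(), atol=1e-8)
        # sklearn's std excludes the noise term
        np.testing.assert_allclose(np.sqrt(v - n2), sd_sk, atol=1e-6)
        ll_sk = gp.log_marginal_likelihood_value_
        assert res.llf == pytest.approx(ll_sk, abs=1e-6)


class TestMarginalLikelihood:
    def test_scalar_case_closed_form(self):
        model = GaussianProcess([[0.0]], [0.0])
        th = theta1(s2=2.0, n2=0.5)
        expected = -0.5 * np.log(2.5) - 0.5 * np.log(2 * np.pi)
        assert model.loglike(th) == pytest.approx(expected, abs=1e-12)

    def test_three_terms_sum_to_loglike(self, rng):
        X = rng.normal(size=(10, 1))
        y = rng.normal(size=10)
        model = GaussianProcess(X, y)
        th = theta1(ls=0.8, s2=1.1, n2=0.2)
        terms = model.loglike_terms(th)
        assert sum(terms.values()) == pytest.approx(model.loglike(th), abs=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.uniform(0, 5, size=(8, 2))
        y = rng.normal(size=8)
        model = GaussianProcess(X, y)
        v0 = theta1(s2=1.4, n2=0.3).to_log_vector()
        v0 = np.log([1.4, 0.9, 2.1, 0.3])
        _, grad = model.loglike_and_grad(v0)
        eps = 1e-6
        for k in range(len(v0)):
            vp, vm = v0.copy(), v0.copy()
            vp[k] += eps
            vm[k] -= eps
            fd = (model.loglike(GPRHyperparams.from_log_vector(vp))
                  - model.loglike(GPRHyperparams.from_log_vector(vm))) / (2 * eps)
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestFit:
    def test_optimization_does_not_decrease_loglike(self, rng):
        X = rng.uniform(0, 100, size=(40, 1))
        y = np.sin(X[:, 0] / 10) + 0.1 * rng.normal(size=40)
        model = GaussianProcess(X, y)
        init = model.default_init()
        res = model.fit(init=init, seed=0)
        assert res.llf >= model.loglike(init) - 1e-8

    def test_deterministic_under_seed(self, rng):
        X = rng.uniform(0, 50, size=(30, 1))
        y = np.cos(X[:, 0] / 5) + 0.05 * rng.normal(size=30)
        r1 = fit_gpr(X, y, seed=7)
        r2 = fit_gpr(X, y, seed=7)
        assert r1.theta.lengthscales[0] == r2.theta.lengthscales[0]
        assert r1.llf == r2.llf

    def test_lengthscale_recovery_from_known_gp(self):
        """Data drawn from a GP with sigma_t=20 d, sigma_s2=4, sigma_n2=0.04:
        the fitted lengthscale lands within a factor of 2 in >=90% of 20
        seeded replicates."""
        true = GPRHyperparams(4.0, [20.0], 0.04)
        t = np.linspace(0, 1000, 200)[:, None]
        K = se_kernel(t, t, true) + true.sigma_n2 * np.eye(200)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(200))
        hits = 0
        for rep in range(20):
            y = L @ np.random.default_rng(rep).normal(size=200)
            res = fit_gpr(t, y, seed=rep)
            ls = res.theta.lengthscales[0]
            hits += 10.0 <= ls <= 40.0
        assert hits >= 18

    def test_duplicating_data_does_not_hurt_holdout(self, rng):
        t = rng.uniform(0, 300, size=60)
        f = lambda x: 3 * np.sin(x / 25)
        y = f(t) + 0.2 * rng.normal(size=60)
        tr, te = t[:40], t[40:]
        ytr, yte = y[:40], y[40:]
        r1 = fit_gpr(tr[:, None], ytr, seed=0)
        r2 = fit_gpr(np.concatenate([tr, tr])[:, None],
                     np.concatenate([ytr, ytr]), seed=0)
        rmse1 = np.sqrt(np.mean((r1.predict(te[:, None])[0] - yte) ** 2))
        rmse2 = np.sqrt(np.mean((r2.predict(te[:, None])[0] - yte) ** 2))
        assert rmse2 <= rmse1 * 1.1

    def test_fit_requires_two_points(self):
        with pytest.raises(ValueError, match="N >= 2"):
            GaussianProcess([[1.0]], [1.0]).fit()


def test_save_load_roundtrip(tmp_path, rng):
    X = rng.normal(size=(12, 2))
    y = rng.normal(size=12)
    res = fit_gpr(X, y, seed=0, input_names=["a", "b"],
                  metadata={"dialect": "test"})
    path = tmp_path / "model.json"
    res.save(path)
    back = GPRResults.load(path)
    m1, v1 = res.predict(X[:3])
    m2, v2 = back.predict(X[:3])
    np.testing.assert_allclose(m1, m2, atol=1e-12)
    np.testing.assert_allclose(v1, v2, atol=1e-12)
    assert back.model.metadata["dialect"] == "test"
    assert "relevance" in res.summary()
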