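import numpy as np
import pytest

from envtrf.errors import DegenerateInputError, InvalidInputError, InvalidParameterError
from envtrf.frontend import EnvelopeSignal
from envtrf.trf import (
    LagSpec,
    batch_fit,
    fit_ridge,
    fit_subject_trf,
    grand_average,
    lag_matrix,
    loo_lambda_search,
    predict,
    score,
    select_lambda_joint,
)


class TestLagSpec:
    def test_default_window_has_181_lags(self):
        spec = LagSpec(-100, 600, 256)
        assert spec.lag_indices[0] == -26  # floor(-25.6)
        assert spec.lag_indices[-1] == 154  # ceil(153.6)
        assert spec.n_lags == 181

    def test_inverted_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            LagSpec(600, -100, 256)


class TestLagMatrix:
    def test_unit_impulse(self):
        X = lag_matrix([1, 0, 0], np.array([0, 1]))
        np.testing.assert_array_equal(X, [[1, 0], [0, 1], [0, 0]])

    def test_negative_lag_shifts_forward(self):
        X = lag_matrix([1, 2, 3], np.array([-1]))
        np.testing.assert_array_equal(X[:, 0], [2, 3, 0])

    def test_zero_envelope_gives_zero_matrix(self):
        assert not lag_matrix(np.zeros(10), np.arange(-2, 3)).any()


class TestFitRidge:
    def test_huge_lambda_shrinks_weights_to_zero(self, rng):
        X = rng.standard_normal((50, 5))
        Y = rng.standard_normal((50, 3))
        model = fit_ridge(X, Y, 1e12)
        assert np.abs(model.weights).max() < 1e-6

    def test_noiseless_interpolation_at_lambda_zero(self, rng):
        X = rng.standard_normal((60, 8))
        W_true = rng.standard_normal((8, 4))
        model = fit_ridge(X, X @ W_true, 0.0)
        np.testing.assert_allclose(model.weights, W_true.T, atol=1e-8)
        np.testing.assert_allclose(model.intercept, 0.0, atol=1e-8)

    def test_three_lag_toy_matches_explicit_normal_equations(self):
        X = np.array([[1.0, 0, 2], [0, 1, 1], [2, 1, 0], [1, 2, 1]])
        Y = np.array([[1.0], [2.0], [0.0], [3.0]])
        lam = 0.5
        model = fit_ridge(X, Y, lam)
        # independent brute-force solve of the augmented system
        Xa = np.column_stack([np.ones(4), X])
        G = Xa.T @ Xa
        m = np.diag(G)[1:].mean()
        P = np.eye(4)
        P[0, 0] = 0.0
        W = np.linalg.solve(G + lam * m * P, Xa.T @ Y)
        np.testing.assert_allclose(model.weights[0], W[1:, 0], atol=1e-12)

    def test_rank_deficient_at_zero_lambda_advises_regularization(self):
        X = np.ones((10, 3))  # rank 1
        with pytest.raises(DegenerateInputError, match="lambda"):
            fit_ridge(X, np.ones((10, 1)), 0.0)

    def test_monotone_shrinkage(self, rng):
        X = rng.standard_normal((40, 12))
        Y = rng.standard_normal((40, 2))
        norms = [
            np.linalg.norm(fit_ridge(X, Y, lam).weights) for lam in 10.0 ** np.arange(-3, 7)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestRidgeOracle:
    def test_matches_augmented_least_squares(self, rng):
        """Ridge via normal equations equals an independent QR-based solve
        of the augmented least-squares system on random 20 x 181 designs."""
        spec = LagSpec(-100, 600, 256)
        for _ in range(5):
            X = rng.standard_normal((20, spec.n_lags))
            Y = rng.standard_normal((20, 4))
            lam = 10.0 ** rng.uniform(-2, 3)
            model = fit_ridge(X, Y, lam, lag_spec=spec)
            Xa = np.column_stack([np.ones(20), X])
            m = np.mean(np.sum(X**2, axis=0))
            aug = np.vstack([Xa, np.sqrt(lam * m) * np.eye(spec.n_lags + 1)[1:]])
            Yaug = np.vstack([Y, np.zeros((spec.n_lags, 4))])
            W_lstsq, *_ = np.linalg.lstsq(aug, Yaug, rcond=None)
            rel = np.abs(model.weights - W_lstsq[1:].T).max() / np.abs(W_lstsq).max()
            assert rel < 1e-8


class TestLooLambdaSearch:
    def _noiseless(self, rng, n_items=4, n_ch=3, n_t=200):
        spec = LagSpec(0, 100, 256)
        envs = [rng.random(n_t) for _ in range(n_items)]
        W = rng.standard_normal((n_ch, spec.n_lags))
        resp = np.stack([(lag_matrix(e, spec.lag_indices) @ W.T).T for e in envs])
        return spec, envs, resp

    def test_noiseless_prefers_smallest_lambda(self, rng):
        spec, envs, resp = self._noiseless(rng)
        res = loo_lambda_search(envs, resp, spec, grid=[1e-6, 1e-2, 1.0, 100.0],
                                normalize=False)
        assert res.best_lambda == 1e-6
        assert np.all(np.diff(res.cv_mse) >= -1e-12)  # nondecreasing in lambda

    def test_fewer_than_two_items_rejected(self, rng):
        spec, envs, resp = self._noiseless(rng, n_items=1)
        with pytest.raises(InvalidInputError):
            loo_lambda_search(envs, resp, spec)

    def test_negative_grid_rejected(self, rng):
        spec, envs, resp = self._noiseless(rng)
        with pytest.raises(InvalidParameterError):
            loo_lambda_search(envs, resp, spec, grid=[-1.0, 1.0])

    def test_joint_selection_minimizes_mean_curve(self, rng):
        spec, envs, resp = self._noiseless(rng)
        a = loo_lambda_search(envs, resp, spec, grid=[1e-3, 1.0], normalize=False)
        noisy = resp + rng.standard_normal(resp.shape)
        b = loo_lambda_search(envs, noisy, spec, grid=[1e-3, 1.0], normalize=False)
        joint = select_lambda_joint(a, b)
        mean_curve = (a.cv_mse + b.cv_mse) / 2
        assert joint == a.grid[np.argmin(mean_curve)]


class TestPredictScore:
    def test_perfect_prediction(self, rng):
        x = rng.standard_normal((100, 3))
        m = score(x, x)
        assert m.pearson_r == pytest.approx(1.0)
        assert m.mse == pytest.approx(0.0)

    def test_anticorrelated_prediction(self, rng):
        x = rng.standard_normal((100, 2))
        assert score(-x, x).pearson_r == pytest.approx(-1.0)

    def test_constant_prediction_flagged_as_missing(self, rng):
        x = rng.standard_normal((50, 2))
        m = score(np.zeros_like(x), x)
        assert np.isnan(m.per_channel_r).all()
        assert np.isnan(m.pearson_r)

    def test_predict_applies_kernel(self, rng):
        spec = LagSpec(0, 50, 256)
        env = EnvelopeSignal(rng.random(100), 256.0)
        W = rng.standard_normal((2, spec.n_lags))
        from envtrf.trf import TRFModel

        model = TRFModel(W, np.zeros(2), spec, 0.0, normalized=False)
        pred = predict(model, env)
        expected = lag_matrix(env.values, spec.lag_indices) @ W.T
        np.testing.assert_allclose(pred, expected)


class TestGrandAverage:
    def _model(self, W, spec):
        from envtrf.trf import TRFModel

        return TRFModel(W, np.zeros(W.shape[0]), spec, 1.0)

    def test_single_model_is_its_own_average(self, rng):
        spec = LagSpec(0, 50, 256)
        m = self._model(rng.standard_normal((2, spec.n_lags)), spec)
        np.testing.assert_array_equal(grand_average([m]).weights, m.weights)

    def test_opposite_models_cancel(self, rng):
        spec = LagSpec(0, 50, 256)
        W = rng.standard_normal((2, spec.n_lags))
        ga = grand_average([self._model(W, spec), self._model(-W, spec)])
        np.testing.assert_allclose(ga.weights, 0.0, atol=1e-15)

    def test_mismatched_axes_rejected(self, rng):
        a = self._model(rng.standard_normal((2, LagSpec(0, 50, 256).n_lags)),
                        LagSpec(0, 50, 256))
        b = self._model(rng.standard_normal((2, LagSpec(0, 100, 256).n_lags)),
                        LagSpec(0, 100, 256))
        with pytest.raises(InvalidInputError):
            grand_average([a, b])


def test_batch_fit_equals_per_subject_fit(small_study):
    cfg = small_study.config
    W = batch_fit(small_study.envelopes, small_study.responses, cfg.lag_spec, 2.0,
                  onset_index=cfg.onset_index)
    m = fit_subject_trf(small_study.envelopes, small_study.responses[2, 1],
                        cfg.lag_spec, 2.0, onset_index=cfg.onset_index)
    np.testing.assert_allclose(W[2, 1], m.weights, atol=1e-10)
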