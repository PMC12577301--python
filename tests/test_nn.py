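"""The volumetric CNN stack: shapes, gradients, losses, optimizer, training."""

import numpy as np
import pytest
from scipy import ndimage

from fogpet.nn import (Adam, TrainConfig, build_cnn2d, build_cnn3d, mse_loss, nll_loss,
                       predict, train_model)
from fogpet.nn.layers import ConvND, Linear, MaxPoolND


class TestArchitecture:
    @pytest.mark.parametrize("shape,flat", [((64, 64, 64), 32768), ((32, 32, 32), 4096),
                                            ((16, 16, 16), 512), ((8, 16, 24), 384)])
    def test_flatten_length_from_halving_arithmetic(self, shape, flat):
        model = build_cnn3d(shape, "classify", seed=0)
        assert model.flatten_length == flat

    def test_forward_shapes_and_probability_normalization(self):
        model = build_cnn3d((16, 16, 16), "classify", seed=0)
        x = np.random.default_rng(0).normal(size=(3, 1, 16, 16, 16)).astype(np.float32)
        logp = model.forward(x)
        assert logp.shape == (3, 2)
        np.testing.assert_allclose(np.exp(logp).sum(axis=1), 1.0, rtol=1e-5)

    def test_regressor_scalar_output_finite(self):
        model = build_cnn3d((16, 16, 16), "regress", seed=0)
        x = np.random.default_rng(0).normal(size=(2, 1, 16, 16, 16)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (2, 1) and np.isfinite(out).all()

    def test_bad_input_dims_rejected(self):
        with pytest.raises(ValueError):
            build_cnn3d((12, 16, 16), "classify")
        with pytest.raises(ValueError):
            build_cnn3d((4, 4, 4), "classify")

    def test_zeroed_final_layer_gives_uniform_probabilities(self):
        model = build_cnn3d((8, 8, 8), "classify", seed=1)
        model.layers[-2].params["W"][:] = 0.0
        model.layers[-2].params["b"][:] = 0.0
        probs = predict(model, np.random.default_rng(0).normal(size=(4, 1, 8, 8, 8)))
        np.testing.assert_allclose(probs, 0.5, atol=1e-7)


class TestConvOracle:
    def test_forward_matches_scipy_correlate(self):
        rng = np.random.default_rng(0)
        conv = ConvND(2, 3, ndim=3, rng=rng)
        X = rng.normal(size=(2, 2, 6, 6, 6)).astype(np.float32)
        out = conv.forward(X)
        W, b = conv.params["W"], conv.params["b"]
        for bi in range(2):
            for o in range(3):
                ref = sum(ndimage.correlate(X[bi, c].astype(float), W[o, c].astype(float),
                                            mode="constant") for c in range(2)) + b[o]
                np.testing.assert_allclose(out[bi, o], ref, atol=1e-5)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        conv = ConvND(1, 2, ndim=3, rng=rng)
        X = rng.normal(size=(2, 1, 5, 5, 5)).astype(np.float32)
        R = rng.normal(size=(2, 2, 5, 5, 5)).astype(np.float32)

        def loss():
            return float((R * conv.forward(X)).sum())

        loss()
        dx = conv.backward(R)
        W = conv.params["W"]
        for _ in range(6):
            ix = tuple(rng.integers(0, s) for s in W.shape)
            eps, old = 1e-2, W[ix]
            W[ix] = old + eps; lp = loss()
            W[ix] = old - eps; lm = loss()
            W[ix] = old
            conv.forward(X); conv.backward(R)
            assert conv.grads["W"][ix] == pytest.approx((lp - lm) / (2 * eps), abs=5e-3)
        for _ in range(6):
            ix = tuple(rng.integers(0, s) for s in X.shape)
            eps, old = 1e-2, X[ix]
            X[ix] = old + eps; lp = loss()
            X[ix] = old - eps; lm = loss()
            X[ix] = old
            assert dx[ix] == pytest.approx((lp - lm) / (2 * eps), abs=5e-3)


class TestPooling:
    def test_pool_reduces_and_takes_window_max(self):
        pool = MaxPoolND(ndim=3)
        x = np.arange(4**3, dtype=np.float32).reshape(1, 1, 4, 4, 4)
        out = pool.forward(x)
        assert out.shape == (1, 1, 2, 2, 2)
        assert out[0, 0, 0, 0, 0] == x[0, 0, :2, :2, :2].max()
        assert out[0, 0, 1, 1, 1] == x[0, 0, 2:, 2:, 2:].max()

    def test_pool_gradient_conserved_under_ties(self):
        pool = MaxPoolND(ndim=2)
        x = np.ones((1, 1, 4, 4), dtype=np.float32)  # every window fully tied
        pool.forward(x)
        dout = np.full((1, 1, 2, 2), 2.0, dtype=np.float32)
        dx = pool.backward(dout)
        assert dx.sum() == pytest.approx(dout.sum())
        assert ((dx == 0) | (dx == 2.0)).all()


class TestLosses:
    def test_nll_hand_computed_two_sample_batch(self):
        logp = np.log(np.array([[0.8, 0.2], [0.3, 0.7]], dtype=np.float32))
        loss, _ = nll_loss(logp, np.array([0, 1]))
        assert loss == pytest.approx(-(np.log(0.8) + np.log(0.7)) / 2, rel=1e-6)

    def test_mse_hand_computed(self):
        loss, _ = mse_loss(np.array([[2.0], [1.0]], dtype=np.float32), np.array([1.0, 3.0]))
        assert loss == pytest.approx((1.0 + 4.0) / 2)


class TestAdam:
    def test_doubling_weight_decay_doubles_penalty_component(self):
        rng = np.random.default_rng(0)
        lin = Linear(4, 3, rng)

        class Tiny:
            layers = [lin]

        lin.grads = {k: np.zeros_like(v) for k, v in lin.params.items()}
        opt1 = Adam(Tiny(), weight_decay=2e-3)
        opt2 = Adam(Tiny(), weight_decay=4e-3)
        g1 = opt1.effective_grad(0, "W")
        g2 = opt2.effective_grad(0, "W")
        np.testing.assert_allclose(g2, 2.0 * g1, rtol=1e-6)
        np.testing.assert_allclose(g1, 2e-3 * lin.params["W"], rtol=1e-6)

    def test_invalid_hyperparameters_rejected(self):
        rng = np.random.default_rng(0)

        class Tiny:
            layers = [Linear(2, 2, rng)]

        with pytest.raises(ValueError):
            Adam(Tiny(), lr=0.0)


class TestTraining:
    def _toy_volumes(self, n, rng, signal=True):
        X = rng.normal(size=(n, 1, 8, 8, 8)).astype(np.float32)
        y = rng.integers(0, 2, size=n)
        if signal:
            X[y == 1, :, 2:6, 2:6, 2:6] += 3.0
        return X, y

    def test_separable_patterns_reach_perfect_validation(self):
        successes = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X, y = self._toy_volumes(40, rng)
            cfg = TrainConfig(max_epochs=60, patience=60, seed=seed)
            model = build_cnn3d((8, 8, 8), "classify", seed=seed)
            model, hist = train_model(model, X[:30], y[:30], X[30:], y[30:], cfg)
            if hist.best_val == 1.0:
                successes += 1
        assert successes >= 2

    def test_no_signal_triggers_early_stopping(self):
        rng = np.random.default_rng(0)
        X = np.zeros((30, 1, 8, 8, 8), dtype=np.float32)
        y = rng.integers(0, 2, size=30)
        cfg = TrainConfig(max_epochs=300, patience=5, seed=0)
        model = build_cnn3d((8, 8, 8), "classify", seed=0)
        model, hist = train_model(model, X[:22], y[:22], X[22:], y[22:], cfg)
        assert hist.stopped_early
        assert len(hist.train_loss) <= 5 + 10  # best epoch early + patience

    def test_fixed_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(1)
        X, y = self._toy_volumes(24, rng)
        cfg = TrainConfig(max_epochs=5, patience=5, seed=3, stop_when_perfect=False)
        runs = []
        for _ in range(2):
            model = build_cnn3d((8, 8, 8), "classify", seed=3)
            model, hist = train_model(model, X[:18], y[:18], X[18:], y[18:], cfg)
            runs.append(hist.train_loss)
        assert runs[0] == runs[1]

    def test_selected_model_is_validation_best(self):
        rng = np.random.default_rng(2)
        X, y = self._toy_volumes(30, rng)
        cfg = TrainConfig(max_epochs=25, patience=25, seed=2)
        model = build_cnn3d((8, 8, 8), "classify", seed=2)
        model, hist = train_model(model, X[:22], y[:22], X[22:], y[22:], cfg)
        out = model.forward(X[22:].astype(np.float32))
        acc = float((out.argmax(1) == y[22:]).mean())
        assert acc == pytest.approx(hist.best_val)

    def test_empty_split_rejected(self):
        model = build_cnn3d((8, 8, 8), "classify", seed=0)
        X = np.zeros((4, 1, 8, 8, 8), dtype=np.float32)
        with pytest.raises(ValueError):
            train_model(model, X, [0, 1, 0, 1], X[:0], [], TrainConfig())

    def test_regression_training_reduces_validation_mse(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 1, 8, 8, 8)).astype(np.float32)
        y = X[:, 0, 2:6, 2:6, 2:6].mean(axis=(1, 2, 3)) * 10.0
        cfg = TrainConfig(max_epochs=40, patience=40, seed=4)
        model = build_cnn3d((8, 8, 8), "regress", seed=4)
        model, hist = train_model(model, X[:22], y[:22], X[22:], y[22:], cfg)
        assert hist.best_val < hist.val_metric[0]


class Test2DBaselineNet:
    def test_shapes_and_probs(self):
        model = build_cnn2d((32, 32), "classify", seed=0)
        assert model.flatten_length == 32 * 8 * 8
        x = np.random.default_rng(0).normal(size=(2, 1, 32, 32)).astype(np.float32)
        logp = model.forward(x)
        np.testing.assert_allclose(np.exp(logp).sum(axis=1), 1.0, rtol=1e-5)
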