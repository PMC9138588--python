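"""Forward correctness, analytic gradients, and training behavior."""

import numpy as np
import pytest

from dtiforge.cnn import (
    CNNConfig,
    build_cnn,
    cnn_extract,
    cnn_forward,
    cnn_loss,
    cnn_train,
    load_checkpoint,
    save_checkpoint,
    _forward_batch,
    _softmax,
)
from dtiforge.errors import DivergenceError, ShapeError


# --- brute-force oracles --------------------------------------------------

def conv_loop(x, w, b):
    """Four-nested-loop valid cross-correlation; x (C,H,W), w (O,C,k,k)."""
    co, ci, k, _ = w.shape
    _, h, wd = x.shape
    out = np.zeros((co, h - k + 1, wd - k + 1))
    for o in range(co):
        for r in range(h - k + 1):
            for c in range(wd - k + 1):
                acc = 0.0
                for ch in range(ci):
                    for i in range(k):
                        for j in range(k):
                            acc += x[ch, r + i, c + j] * w[o, ch, i, j]
                out[o, r, c] = acc + b[o]
    return out


def pool_loop(x, p, mode):
    c, h, w = x.shape
    out = np.zeros((c, h // p, w // p))
    for ch in range(c):
        for r in range(h // p):
            for cc in range(w // p):
                tile = x[ch, r * p:(r + 1) * p, cc * p:(cc + 1) * p]
                out[ch, r, cc] = tile.mean() if mode == "mean" else tile.max()
    return out


def loss_and_grads(m, X, y):
    """Analytic loss + per-parameter gradients, same math as cnn_train."""
    n = len(y)
    trace = _forward_batch(m, X)
    p = _softmax(trace[-1])
    loss = -float(np.mean(np.log(p[np.arange(n), y])))
    loss += 0.5 * m.config.theta * sum(float((w ** 2).sum()) for w in m.weights)
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), y] = 1.0
    grad = (p - onehot) / n
    for lay in reversed(m.layers):
        grad = lay.backward(grad)
    return loss, [
        (lay.dw + m.config.theta * lay.w, lay.db)
        for lay in m.layers
        if lay.has_weights
    ]


class TestForward:
    def test_identity_kernel_passes_input_through(self, rng):
        cfg = CNNConfig(
            layers=[("conv", 1, 1), ("dense", 2)],
            input_shape=(1, 6, 6),
            activation="identity",
        )
        m = build_cnn(cfg)
        m.layers[0].w[:] = 1.0
        m.layers[0].b[:] = 0.0
        x = rng.normal(size=(6, 6))
        _, trace = cnn_forward(m, x)
        assert np.allclose(trace[0][0], x)

    def test_zero_weights_yield_constant_bias_map(self, rng):
        cfg = CNNConfig(
            layers=[("conv", 3, 3), ("dense", 2)],
            input_shape=(1, 6, 6),
            activation="identity",
        )
        m = build_cnn(cfg)
        m.layers[0].w[:] = 0.0
        m.layers[0].b[:] = np.array([0.5, -1.0, 2.0])
        _, trace = cnn_forward(m, rng.normal(size=(6, 6)))
        for ch, beta in enumerate((0.5, -1.0, 2.0)):
            assert np.allclose(trace[0][ch], beta)

    def test_random_kernel_matches_nested_loop_oracle(self, rng):
        cfg = CNNConfig(
            layers=[("conv", 1, 3), ("dense", 2)],
            input_shape=(1, 6, 6),
            activation="identity",
            seed=3,
        )
        m = build_cnn(cfg)
        x = rng.normal(size=(1, 6, 6))
        _, trace = cnn_forward(m, x)
        assert np.allclose(trace[0], conv_loop(x, m.layers[0].w, m.layers[0].b),
                           atol=1e-10)

    @pytest.mark.parametrize("pooling", ["mean", "max"])
    def test_full_stack_matches_oracle_many_instances(self, pooling):
        """Conv + pool + dense forward vs brute-force on 25+25 instances."""
        rng = np.random.default_rng(99)
        for trial in range(25):
            h = int(rng.integers(6, 11))
            k = int(rng.integers(1, 4))
            c_out = int(rng.integers(1, 4))
            cfg = CNNConfig(
                layers=[("conv", c_out, k), ("subsample", 2), ("dense", 2)],
                input_shape=(1, h, h),
                activation="identity",
                pooling=pooling,
                seed=trial,
            )
            m = build_cnn(cfg)
            x = rng.normal(size=(1, h, h))
            _, trace = cnn_forward(m, x)
            conv_ref = conv_loop(x, m.layers[0].w, m.layers[0].b)
            pool_ref = pool_loop(conv_ref, 2, pooling)
            dense_ref = pool_ref.ravel() @ m.layers[2].w + m.layers[2].b
            assert np.allclose(trace[0], conv_ref, atol=1e-10)
            assert np.allclose(trace[1], pool_ref, atol=1e-10)
            assert np.allclose(trace[2], dense_ref, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        m = build_cnn(CNNConfig())
        with pytest.raises(ShapeError):
            cnn_forward(m, np.zeros((5, 5)))


class TestLoss:
    def small_model(self, theta=0.0, seed=0):
        return build_cnn(CNNConfig(
            layers=[("conv", 2, 3), ("dense", 2)],
            input_shape=(1, 5, 5),
            theta=theta,
            seed=seed,
        ))

    def test_theta_zero_is_pure_data_term(self, rng):
        m = self.small_model(theta=0.0)
        X = rng.normal(size=(4, 1, 5, 5))
        y = np.array([0, 1, 0, 1])
        logits = _forward_batch(m, X)[-1]
        p = _softmax(logits)
        expected = -np.mean(np.log(p[np.arange(4), y]))
        assert np.isclose(cnn_loss(m, (X, y)), expected, atol=1e-12)

    def test_zero_weights_zero_penalty(self, rng):
        m = self.small_model(theta=5.0)
        for lay in m.layers:
            if lay.has_weights:
                lay.w[:] = 0.0
        X = rng.normal(size=(3, 1, 5, 5))
        y = np.array([0, 1, 1])
        # data term of an all-zero net is exactly log 2
        assert np.isclose(cnn_loss(m, (X, y)), np.log(2.0), atol=1e-12)

    def test_penalty_matches_explicit_summation(self, rng):
        m = self.small_model(theta=0.1, seed=5)
        X = rng.normal(size=(3, 1, 5, 5))
        y = np.array([1, 0, 1])
        m0 = self.small_model(theta=0.0, seed=5)
        sum_sq = 0.0
        for w in m.weights:
            for v in w.ravel():
                sum_sq += float(v) * float(v)
        assert np.isclose(
            cnn_loss(m, (X, y)) - cnn_loss(m0, (X, y)), 0.05 * sum_sq, atol=1e-12
        )


class TestGradients:
    @pytest.mark.parametrize(
        "activation,pooling",
        [("sigmoid", "mean"), ("tanh", "max"), ("identity", "mean")],
    )
    def test_analytic_vs_central_finite_differences(self, activation, pooling):
        """Gradient check across conv, both pool modes, and dense layers."""
        rng = np.random.default_rng(7)
        cfg = CNNConfig(
            layers=[("conv", 2, 3), ("subsample", 2), ("dense", 6), ("dense", 2)],
            input_shape=(1, 8, 8),
            theta=0.01,
            activation=activation,
            pooling=pooling,
            seed=21,
        )
        m = build_cnn(cfg)
        X = rng.normal(size=(5, 1, 8, 8))
        y = np.array([0, 1, 1, 0, 1])
        _, grads = loss_and_grads(m, X, y)
        weighted = [lay for lay in m.layers if lay.has_weights]
        eps = 1e-5
        checked = 0
        for li, lay in enumerate(weighted):
            for arr, garr in ((lay.w, grads[li][0]), (lay.b, grads[li][1])):
                flat = arr.ravel()
                idxs = rng.choice(flat.size, size=min(7, flat.size), replace=False)
                for i in idxs:
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp = cnn_loss(m, (X, y))
                    flat[i] = orig - eps
                    lm = cnn_loss(m, (X, y))
                    flat[i] = orig
                    fd = (lp - lm) / (2 * eps)
                    g = garr.ravel()[i]
                    rel = abs(g - fd) / max(1e-8, abs(g) + abs(fd))
                    assert rel < 1e-5, f"layer {li}: grad {g} vs fd {fd}"
                    checked += 1
        assert checked >= 20


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_untouched(self, rng):
        cfg = CNNConfig(epsilon=0.0, epochs=10, seed=4)
        m = build_cnn(cfg)
        before = [w.copy() for w in m.weights] + [b.copy() for b in m.biases]
        X = rng.normal(size=(6, 1, 20, 20))
        y = np.array([0, 1, 0, 1, 0, 1])
        cnn_train(m, (X, y))
        after = list(m.weights) + list(m.biases)
        for b_arr, a_arr in zip(before, after):
            assert np.array_equal(b_arr, a_arr)

    def test_loss_non_increasing_on_separable_data(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([
            rng.normal(loc=-1.0, size=(4, 1, 8, 8)),
            rng.normal(loc=1.0, size=(4, 1, 8, 8)),
        ])
        y = np.array([0] * 4 + [1] * 4)
        cfg = CNNConfig(
            layers=[("conv", 2, 3), ("subsample", 2), ("dense", 4), ("dense", 2)],
            input_shape=(1, 8, 8),
            epsilon=0.01,
            epochs=1,
            seed=9,
            activation="sigmoid",
        )
        m = build_cnn(cfg)
        losses = [cnn_loss(m, (X, y))]
        for _ in range(30):
            cnn_train(m, (X, y))
            losses.append(cnn_loss(m, (X, y)))
        diffs = np.diff(losses)
        assert (diffs <= 1e-12).all()

    def test_strong_regularization_shrinks_weights(self, rng):
        X = rng.normal(size=(8, 1, 8, 8))
        y = np.array([0, 1] * 4)
        norms = {}
        for theta in (0.0, 1e3):
            cfg = CNNConfig(
                layers=[("conv", 2, 3), ("subsample", 2), ("dense", 2)],
                input_shape=(1, 8, 8),
                theta=theta,
                epsilon=1e-4,
                epochs=30,
                seed=13,
            )
            m = cnn_train(build_cnn(cfg), (X, y))
            norms[theta] = np.sqrt(sum((w ** 2).sum() for w in m.weights))
        assert norms[1e3] < norms[0.0]

    def test_divergence_raises_with_epoch(self, rng):
        cfg = CNNConfig(
            layers=[("conv", 2, 3), ("dense", 2)],
            input_shape=(1, 6, 6),
            epsilon=1e8,
            epochs=50,
            seed=2,
        )
        m = build_cnn(cfg)
        X = rng.normal(size=(4, 1, 6, 6))
        y = np.array([0, 1, 0, 1])
        with np.errstate(all="ignore"), pytest.raises(DivergenceError):
            cnn_train(m, (X, y))


class TestExtract:
    def test_deterministic_and_default_width(self, rng):
        m = build_cnn(CNNConfig(seed=1))
        x = rng.normal(size=(20, 20))
        f1, f2 = cnn_extract(m, x), cnn_extract(m, x)
        assert f1.shape == (128,)
        assert np.array_equal(f1, f2)

    def test_equals_forward_trace_at_penultimate_layer(self, rng):
        m = build_cnn(CNNConfig(seed=1))
        x = rng.normal(size=(20, 20))
        _, trace = cnn_forward(m, x)
        assert np.array_equal(cnn_extract(m, x), trace[-2])


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        m = build_cnn(CNNConfig(seed=8, theta=0.3, pooling="max"))
        X = rng.normal(size=(4, 1, 20, 20))
        cnn_train(m, (X, np.array([0, 1, 1, 0])),
                  CNNConfig(epochs=2, epsilon=0.01))
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        m2 = load_checkpoint(path)
        assert m2.config == m.config
        for w1, w2 in zip(m.weights, m2.weights):
            assert np.array_equal(w1, w2)
        x = rng.normal(size=(20, 20))
        assert np.array_equal(cnn_extract(m, x), cnn_extract(m2, x))
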