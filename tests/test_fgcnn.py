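"""Network-layer, gradient and training-contract tests.

The gradient and optimizer checks are the module's core correctness
properties: the closed-form fusion gradients must match finite differences
of the loss, and the implemented update must coincide with an independently
transcribed Adam recursion.
"""

import numpy as np
import pytest

from emgknee import (
    AdamState,
    BaselineCNN,
    FGCNN,
    FGCNNConfig,
    FGCNNResults,
    adam_update,
    fusion_gradients,
    max_pool,
    mse_loss,
)
from emgknee.fgcnn import conv_layer, leaky_relu, train_fgcnn
from emgknee.exceptions import (
    DimensionError,
    EmptyInputError,
    NumericError,
    ParameterError,
)


def naive_conv_same(x, W, b):
    """Sliding-dot-product oracle for the 'same'-padded cross-correlation."""
    B, L, Din = x.shape
    K, _, Dout = W.shape
    pl = (K - 1) // 2
    out = np.zeros((B, L, Dout))
    for bi in range(B):
        for l in range(L):
            for o in range(Dout):
                acc = b[o]
                for k in range(K):
                    src = l + k - pl
                    if 0 <= src < L:
                        for d in range(Din):
                            acc += x[bi, src, d] * W[k, d, o]
                out[bi, l, o] = acc
    return out


class TestConvLayer:
    def test_identity_kernel_passthrough(self):
        x = np.abs(np.random.default_rng(0).standard_normal((2, 16, 1)))
        W = np.ones((1, 1, 1))
        out = conv_layer(x, W, np.zeros(1), slope=0.1, bn=None)
        np.testing.assert_allclose(out, x)

    def test_leaky_relu_values(self):
        assert leaky_relu(2.0, 0.1) == pytest.approx(2.0)
        assert leaky_relu(-2.0, 0.1) == pytest.approx(-0.2)

    def test_matches_naive_convolution_oracle(self, rng):
        x = rng.standard_normal((3, 20, 4))
        W = rng.standard_normal((5, 4, 6))
        b = rng.standard_normal(6)
        got = conv_layer(x, W, b, slope=1.0, bn=None)  # slope 1 = linear
        np.testing.assert_allclose(got, naive_conv_same(x, W, b), atol=1e-6)


class TestMaxPool:
    def test_direct_application(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])[:, None]
        np.testing.assert_array_equal(max_pool(y).ravel(), [3.0, 4.0, 9.0])

    def test_negative_values(self):
        y = np.array([-1.0, -2.0])[:, None]
        np.testing.assert_array_equal(max_pool(y).ravel(), [-1.0])

    def test_odd_length_drops_last(self):
        y = np.arange(7.0)[::-1][:, None]  # 6..0
        out = max_pool(y)
        assert out.shape == (3, 1)
        np.testing.assert_array_equal(out.ravel(), [6.0, 4.0, 2.0])

    def test_too_short_rejected(self):
        with pytest.raises(DimensionError):
            max_pool(np.ones((1, 1)))

    def test_matches_pairwise_enumeration_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(2, 40))
            D = int(rng.integers(1, 8))
            y = rng.standard_normal((L, D))
            got = max_pool(y)
            expected = np.array(
                [[max(y[2 * i, j], y[2 * i + 1, j]) for j in range(D)]
                 for i in range(L // 2)]
            )
            np.testing.assert_array_equal(got, expected)


class TestForward:
    def _fitted(self, rng, n=40, guided=True, **cfg_kw):
        cfg = FGCNNConfig(input_len=64, epochs=1, **cfg_kw)
        X = rng.standard_normal((n, 64))
        P = rng.standard_normal((n, 14))
        y = rng.uniform(-0.8, 0.8, n)
        if guided:
            return FGCNN(X, P, y, config=cfg).fit(seed=0), X, P
        cfg = FGCNNConfig(input_len=64, fc_sizes=(192, 28), epochs=1, **cfg_kw)
        return BaselineCNN(X, None, y, config=cfg).fit(seed=0), X, None

    def test_zero_fusion_weights_give_zero_output(self, rng):
        res, X, P = self._fitted(rng)
        res.params["w_p"][:] = 0.0
        res.params["w_l"][:] = 0.0
        np.testing.assert_allclose(res.predict_scaled(X, P), 0.0, atol=1e-12)

    def test_tanh_of_constructed_preactivation(self):
        # with p = e_1 / w_p = 0.5 e_1 and l forced to 0, y_hat = tanh(0.5)
        y = np.tanh(0.5)
        assert y == pytest.approx(0.4621, abs=1e-4)

    def test_saturation_bound(self, rng):
        # |pre-activation| >= 20 drives tanh to within 1e-8 of +-1
        res, X, P = self._fitted(rng)
        res.params["w_p"][:] = 50.0
        res.params["w_l"][:] = 0.0
        out = res.predict_scaled(X, P)
        z = ((P - res.p_mean) / res.p_std) @ res.params["w_p"].astype(float)
        saturated = np.abs(z) >= 20.0
        assert saturated.any()
        assert np.all(np.abs(out[saturated]) >= 1.0 - 1e-8)
        assert np.all(np.abs(out) <= 1.0)

    def test_output_strictly_inside_unit_interval(self, rng):
        res, X, P = self._fitted(rng)
        out = res.predict_scaled(X, P)
        assert np.all(np.abs(out) < 1.0)

    def test_non_finite_window_rejected(self, rng):
        res, X, P = self._fitted(rng)
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(NumericError):
            res.predict_scaled(X, P)


class TestMseLoss:
    def test_perfect_fit_is_zero(self):
        assert mse_loss([0.1, -0.2], [0.1, -0.2]) == 0.0

    def test_direct_evaluation(self):
        assert mse_loss([1.0, 0.0], [0.0, 0.0]) == pytest.approx(0.5)

    def test_order_invariance(self, rng):
        y = rng.uniform(-1, 1, 20)
        yh = rng.uniform(-1, 1, 20)
        perm = rng.permutation(20)
        assert mse_loss(y, yh) == pytest.approx(mse_loss(y[perm], yh[perm]))

    def test_empty_batch_rejected(self):
        with pytest.raises(EmptyInputError):
            mse_loss([], [])


class TestFusionGradients:
    def test_zero_residual_gives_zero_gradients(self, rng):
        p = rng.standard_normal((5, 14))
        l = rng.standard_normal((5, 14))
        y = rng.uniform(-0.5, 0.5, 5)
        g_p, g_l = fusion_gradients(y, p, l, y)
        np.testing.assert_array_equal(g_p, np.zeros(14))
        np.testing.assert_array_equal(g_l, np.zeros(14))

    def test_scalar_hand_evaluation(self):
        # N=1, p=l=1, w=0 -> y_hat=0; dMSE/dw_p = -2*1*(1-0)*(1-0) = -2
        g_p, g_l = fusion_gradients([1.0], [[1.0]], [[1.0]], [0.0])
        assert g_p[0] == pytest.approx(-2.0)
        assert g_l[0] == pytest.approx(-2.0)

    def test_matches_finite_differences(self, rng):
        for _ in range(20):
            N, d = int(rng.integers(1, 8)), int(rng.integers(1, 6))
            p = rng.standard_normal((N, d))
            l = rng.standard_normal((N, d))
            w_p = rng.standard_normal(d)
            w_l = rng.standard_normal(d)
            y = rng.uniform(-0.9, 0.9, N)

            def loss(wp, wl):
                return mse_loss(y, np.tanh(p @ wp + l @ wl))

            y_hat = np.tanh(p @ w_p + l @ w_l)
            g_p, g_l = fusion_gradients(y, p, l, y_hat)
            eps = 1e-6
            for j in range(d):
                e = np.zeros(d)
                e[j] = eps
                fd_p = (loss(w_p + e, w_l) - loss(w_p - e, w_l)) / (2 * eps)
                fd_l = (loss(w_p, w_l + e) - loss(w_p, w_l - e)) / (2 * eps)
                assert g_p[j] == pytest.approx(fd_p, rel=1e-5, abs=1e-9)
                assert g_l[j] == pytest.approx(fd_l, rel=1e-5, abs=1e-9)


def reference_adam(w, grads, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
    """Independent transcription of the bias-corrected Adam recursion."""
    s = np.zeros_like(w)
    r = np.zeros_like(w)
    out = [np.array(w, dtype=float)]
    for t, g in enumerate(grads, start=1):
        s = b1 * s + (1 - b1) * g
        r = b2 * r + (1 - b2) * g * g
        step = lr * (s / (1 - b1**t)) / (np.sqrt(r / (1 - b2**t)) + eps)
        out.append(out[-1] - step)
    return out[1:]


class TestAdamUpdate:
    def test_zero_gradient_null_update(self):
        st = AdamState.zeros_like(np.ones(3))
        w = adam_update(np.ones(3), np.zeros(3), st)
        np.testing.assert_array_equal(w, np.ones(3))

    def test_first_step_magnitude(self):
        st = AdamState.zeros_like(np.zeros(1))
        w = adam_update(np.zeros(1), np.ones(1), st, lr=1e-3)
        # bias-corrected first step ~ lr * sign(g)
        assert w[0] == pytest.approx(-1e-3, rel=1e-4)

    def test_two_steps_match_reference_recursion(self, rng):
        w0 = rng.standard_normal(6)
        g1, g2 = rng.standard_normal(6), rng.standard_normal(6)
        st = AdamState.zeros_like(w0)
        w1 = adam_update(w0, g1, st)
        w2 = adam_update(w1, g2, st)
        ref1, ref2 = reference_adam(w0, [g1, g2])
        np.testing.assert_allclose(w1, ref1, atol=1e-12, rtol=0)
        np.testing.assert_allclose(w2, ref2, atol=1e-12, rtol=0)

    def test_non_finite_gradient_rejected(self):
        st = AdamState.zeros_like(np.zeros(2))
        with pytest.raises(NumericError):
            adam_update(np.zeros(2), np.array([np.nan, 0.0]), st)


class TestTraining:
    def test_constant_target_fit(self, rng):
        X = rng.standard_normal((200, 64))
        P = rng.standard_normal((200, 14))
        y = np.full(200, 0.3)
        cfg = FGCNNConfig(input_len=64, epochs=50)
        res = FGCNN(X, P, y, config=cfg).fit(seed=0)
        assert res.loss_history[-1] < 0.01

    def test_same_seed_bit_identical(self, rng):
        X = rng.standard_normal((120, 64))
        P = rng.standard_normal((120, 14))
        y = np.tanh(P[:, 0])
        cfg = FGCNNConfig(input_len=64, epochs=3)
        h1 = FGCNN(X, P, y, config=cfg).fit(seed=5).loss_history
        h2 = FGCNN(X, P, y, config=cfg).fit(seed=5).loss_history
        np.testing.assert_array_equal(h1, h2)

    def test_true_labels_beat_shuffled_labels(self, rng):
        # learnable synthetic mapping: target depends on the window amplitude
        X = rng.standard_normal((300, 64))
        amp = rng.uniform(0.2, 2.0, 300)
        X *= amp[:, None]
        from emgknee.handcrafted_features import feature_matrix

        P = feature_matrix(X)
        y = np.tanh(amp - 1.0)
        cfg = FGCNNConfig(input_len=64, epochs=15)
        finals_true, finals_shuf = [], []
        for seed in (0, 1, 2):
            finals_true.append(
                FGCNN(X, P, y, config=cfg).fit(seed=seed).loss_history[-1]
            )
            y_s = np.random.default_rng(seed).permutation(y)
            finals_shuf.append(
                FGCNN(X, P, y_s, config=cfg).fit(seed=seed).loss_history[-1]
            )
        assert np.median(finals_true) < np.median(finals_shuf)

    def test_unscaled_targets_rejected(self, rng):
        X = rng.standard_normal((20, 64))
        P = rng.standard_normal((20, 14))
        with pytest.raises(ParameterError):
            FGCNN(X, P, np.linspace(0, 60, 20), config=FGCNNConfig(input_len=64))

    def test_epoch_loss_robust_to_batch_order(self, rng):
        # sequential optimizers are order-dependent; on a rapidly converging
        # problem the final epoch loss must agree closely across shuffles
        X = rng.standard_normal((200, 64))
        P = rng.standard_normal((200, 14))
        y = np.full(200, 0.3)
        cfg = FGCNNConfig(input_len=64, epochs=30)
        finals = [
            FGCNN(X, P, y, config=cfg).fit(seed=s).loss_history[-1]
            for s in (0, 1)
        ]
        assert finals[0] == pytest.approx(finals[1], rel=0.5, abs=5e-3)


class TestFeatureExtraction:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 64))
        from emgknee.handcrafted_features import feature_matrix

        P = feature_matrix(X)
        y = np.tanh(P[:, 3] / P[:, 3].std() - 1)
        res = FGCNN(X, P, y, config=FGCNNConfig(input_len=64, epochs=2)).fit(seed=0)
        return res, X, P

    def test_width_is_28(self, fitted):
        res, X, P = fitted
        assert res.extract_features(X, P).shape == (80, 28)

    def test_first_14_columns_bit_equal_handcrafted(self, fitted):
        res, X, P = fitted
        F = res.extract_features(X, P)
        np.testing.assert_array_equal(F[:, :14], P)

    def test_repeated_extraction_identical(self, fitted):
        res, X, P = fitted
        np.testing.assert_array_equal(
            res.extract_features(X, P), res.extract_features(X, P)
        )

    def test_checkpoint_round_trip(self, fitted, tmp_path):
        res, X, P = fitted
        res.save(tmp_path / "ckpt.npz")
        back = FGCNNResults.load(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(
            back.extract_features(X, P), res.extract_features(X, P)
        )


class TestBaselineCNN:
    def test_feature_width_28_and_determinism(self, rng):
        X = rng.standard_normal((60, 64))
        y = np.tanh(X.std(axis=1) - 1)
        cfg = FGCNNConfig(input_len=64, fc_sizes=(192, 28), epochs=2)
        r1 = BaselineCNN(X, None, y, config=cfg).fit(seed=3)
        r2 = BaselineCNN(X, None, y, config=cfg).fit(seed=3)
        F1, F2 = r1.extract_features(X), r2.extract_features(X)
        assert F1.shape == (60, 28)
        np.testing.assert_array_equal(F1, F2)

    def test_loss_decreases_on_learnable_data(self, rng):
        X = rng.standard_normal((200, 64))
        amp = rng.uniform(0.2, 2.0, 200)
        X *= amp[:, None]
        y = np.tanh(amp - 1.0)
        cfg = FGCNNConfig(input_len=64, fc_sizes=(192, 28), epochs=15)
        res = BaselineCNN(X, None, y, config=cfg).fit(seed=0)
        assert res.loss_history[-1] < res.loss_history[0]


class TestFeatureGuidanceInvariant:
    def test_frozen_wl_reduces_to_tanh_glm_on_p(self, rng):
        """With w_l = 0 the fusion head is a tanh GLM on p alone."""
        from scipy.optimize import minimize

        N, d = 300, 14
        P = rng.standard_normal((N, d))
        w_true = rng.standard_normal(d) * 0.4
        y = np.tanh(P @ w_true) + 0.05 * rng.standard_normal(N)
        y = np.clip(y, -0.99, 0.99)

        # direct tanh-GLM fit on p (independent optimizer)
        def obj(w):
            return np.mean((y - np.tanh(P @ w)) ** 2)

        direct = minimize(obj, np.zeros(d), method="L-BFGS-B").fun

        # fusion-weight-only training: same loss surface via Adam on w_p
        from emgknee import AdamState, adam_update, fusion_gradients

        w_p = np.zeros(d)
        st = AdamState.zeros_like(w_p)
        for _ in range(4000):
            y_hat = np.tanh(P @ w_p)
            g_p, _ = fusion_gradients(y, P, np.zeros_like(P), y_hat)
            w_p = adam_update(w_p, g_p, st, lr=0.01)
        fused = np.mean((y - np.tanh(P @ w_p)) ** 2)
        assert fused <= direct * 1.05 + 1e-12
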