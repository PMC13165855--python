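"""Network blocks against brute-force oracles and their algebraic invariants."""

import numpy as np
import pytest

from dcamnet import _nn
from dcamnet.model import DCAMNet, DCAMNetConfig, aggregate_kernels


def entropy(p):
    p = np.clip(p, 1e-300, None)
    return float(-(p * np.log(p)).sum())


class TestSEAttention:
    def test_constant_input_zero_w1_gives_uniform_weights(self, rng):
        layer = _nn.SEDynamicConv(4, K=3, n_maps=2, kernel_len=3, rng=rng)
        layer.W1.value[...] = 0.0
        pi = layer.attention(np.full((5, 4, 2, 10), 3.7))
        np.testing.assert_allclose(pi, 1.0 / 3.0)

    def test_single_kernel_degenerate(self, rng):
        layer = _nn.SEDynamicConv(4, K=1, n_maps=2, kernel_len=3, rng=rng)
        pi = layer.attention(rng.normal(size=(3, 4, 2, 10)))
        np.testing.assert_array_equal(pi, 1.0)

    def test_hand_evaluation_small_branch(self):
        """Scalar hand computation: 4 bands, bottleneck 2, K=2."""
        layer = _nn.SEDynamicConv(4, K=2, n_maps=1, kernel_len=1, reduction=2, tau=1.0)
        W1 = np.array([[1.0, 0.0, -1.0, 0.0], [0.5, 0.5, 0.0, -0.25]])
        W2 = np.array([[1.0, -1.0], [0.0, 2.0]])
        layer.W1.value[...] = W1
        layer.W2.value[...] = W2
        # band means g = (1, 2, 3, 4) by construction
        x = np.stack([np.full((2, 4), v) for v in (1.0, 2.0, 3.0, 4.0)])[None]
        g = np.array([1.0, 2.0, 3.0, 4.0])
        a = np.maximum(W1 @ g, 0.0)  # = (0, 0.5)
        z = W2 @ a  # = (-0.5, 1.0)
        expected = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(layer.attention(x)[0], expected, atol=1e-12)

    def test_simplex_constraints_on_every_forward(self, tiny_config, rng):
        net = DCAMNet(tiny_config, seed=0)
        for _ in range(3):
            x = rng.normal(size=(7, 4, 3, 50))
            net.forward(x)
            pi = net.conv.last_pi
            assert pi.min() >= 0.0 and pi.max() <= 1.0
            np.testing.assert_allclose(pi.sum(axis=1), 1.0, atol=1e-6)

    def test_entropy_non_increasing_as_temperature_decreases(self, rng):
        layer = _nn.SEDynamicConv(4, K=4, n_maps=2, kernel_len=3, rng=rng)
        x = rng.normal(size=(1, 4, 2, 20))
        ents = []
        for tau in (4.0, 2.0, 1.0, 0.5, 0.1):
            layer.tau = tau
            ents.append(entropy(layer.attention(x)[0]))
        assert all(a >= b - 1e-12 for a, b in zip(ents, ents[1:]))


class TestKernelAggregation:
    def test_one_hot_selects_a_basis_kernel(self, rng):
        W = rng.normal(size=(3, 2, 4, 5))
        b = rng.normal(size=(3, 2))
        w_eff, b_eff = aggregate_kernels(W, b, [0.0, 1.0, 0.0])
        np.testing.assert_array_equal(w_eff, W[1])
        np.testing.assert_array_equal(b_eff, b[1])

    def test_identical_kernels_are_a_fixed_point(self, rng):
        base = rng.normal(size=(2, 4, 5))
        W = np.stack([base] * 4)
        w_eff, _ = aggregate_kernels(W, np.zeros((4, 2)), [0.1, 0.2, 0.3, 0.4])
        np.testing.assert_allclose(w_eff, base, atol=1e-12)

    def test_elementwise_arithmetic(self):
        W = np.arange(2 * 1 * 1 * 2, dtype=float).reshape(2, 1, 1, 2)
        b = np.array([[1.0], [3.0]])
        w_eff, b_eff = aggregate_kernels(W, b, [0.25, 0.75])
        np.testing.assert_allclose(w_eff, 0.25 * W[0] + 0.75 * W[1])
        np.testing.assert_allclose(b_eff, [2.5])

    def test_rejects_off_simplex_weights(self, rng):
        W = rng.normal(size=(2, 1, 1, 2))
        with pytest.raises(ValueError):
            aggregate_kernels(W, np.zeros((2, 1)), [0.7, 0.7])

    def test_convexity_bound_on_effective_kernel(self, rng):
        layer = _nn.SEDynamicConv(3, K=4, n_maps=2, kernel_len=5, rng=rng)
        x = rng.normal(size=(1, 3, 2, 30))
        pi = layer.attention(x)[0]
        w_eff, _ = aggregate_kernels(layer.W.value, layer.b.value, pi)
        lo = layer.W.value.min(axis=0)
        hi = layer.W.value.max(axis=0)
        assert np.all(w_eff >= lo - 1e-12) and np.all(w_eff <= hi + 1e-12)


class TestDynamicConvolution:
    def test_matches_sliding_dot_product_oracle(self, rng):
        """Brute-force loop oracle on a small random tensor."""
        x = rng.normal(size=(2, 3, 2, 8))
        w = rng.normal(size=(4, 3, 3))
        y = _nn.corr_time_same(x, w)
        p = 1
        expected = np.zeros_like(y)
        for b in range(2):
            for m in range(4):
                for c in range(2):
                    for t in range(8):
                        for v in range(3):
                            for l in range(3):
                                if 0 <= t + l - p < 8:
                                    expected[b, m, c, t] += x[b, v, c, t + l - p] * w[m, v, l]
        np.testing.assert_allclose(y, expected, atol=1e-6)

    def test_toy_one_band_kernel(self):
        """1-band, 1-channel, T=4, L=2 with a hand-set kernel."""
        layer = _nn.SEDynamicConv(1, K=1, n_maps=1, kernel_len=2)
        layer.W.value[...] = np.array([1.0, 2.0]).reshape(1, 1, 1, 2)
        layer.b.value[...] = 0.0
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 1, 4)
        y = layer.forward(x)
        # p = 0 for L=2: y[t] = x[t] * 1 + x[t+1] * 2 (zero past the end)
        np.testing.assert_allclose(y.ravel(), [5.0, 8.0, 11.0, 4.0], atol=1e-10)

    def test_zero_weights_give_elu_zero_output(self, tiny_config):
        net = DCAMNet(tiny_config, seed=0)
        net.conv.W.value[...] = 0.0
        net.conv.b.value[...] = 0.0
        x = np.random.default_rng(0).normal(size=(2, 4, 3, 50))
        y = net.layers[0].forward(x)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_valid_padding_shrinks_time_axis(self, rng):
        layer = _nn.SEDynamicConv(2, K=1, n_maps=3, kernel_len=5, padding="valid", rng=rng)
        y = layer.forward(rng.normal(size=(2, 2, 3, 20)))
        assert y.shape == (2, 3, 3, 16)

    def test_k1_dynamic_equals_static_network(self, tiny_config, rng):
        """The full forward with one kernel equals the static ablation variant."""
        full = DCAMNet(tiny_config, variant="full", seed=3)
        static = DCAMNet(tiny_config, variant="static_K1", seed=3)
        # make the full model's K kernels identical to the static kernel
        full.conv.W.value[...] = static.conv.W.value[0]
        full.conv.b.value[...] = static.conv.b.value[0]
        for lf, ls in zip(full.layers[1:], static.layers[1:]):
            for pf, ps in zip(lf.params(), ls.params()):
                pf.value[...] = ps.value
        x = rng.normal(size=(4, 4, 3, 50))
        np.testing.assert_allclose(full.forward(x), static.forward(x), atol=1e-5)


class TestSpatialConvolution:
    def test_indicator_filter_selects_one_series(self, rng):
        layer = _nn.SpatialConv(2, n_maps=3, n_channels=4, rng=rng)
        layer.S.value[...] = 0.0
        layer.S.value[0, 1, 2] = 1.0
        x = rng.normal(size=(2, 3, 4, 6))
        y = layer.forward(x)
        np.testing.assert_allclose(y[:, 0, :], x[:, 1, 2, :], atol=1e-12)

    def test_zero_filters(self, rng):
        layer = _nn.SpatialConv(2, 3, 4, rng=rng)
        layer.S.value[...] = 0.0
        assert np.abs(layer.forward(rng.normal(size=(1, 3, 4, 5)))).max() == 0.0

    def test_matches_explicit_loop_oracle(self, rng):
        layer = _nn.SpatialConv(4, n_maps=2, n_channels=3, rng=rng)
        x = rng.normal(size=(2, 2, 3, 5))
        y = layer.forward(x)
        expected = np.zeros((2, 4, 5))
        for b in range(2):
            for m in range(4):
                for t in range(5):
                    for n in range(2):
                        for c in range(3):
                            expected[b, m, t] += x[b, n, c, t] * layer.S.value[m, n, c]
        np.testing.assert_allclose(y, expected, atol=1e-6)


class TestWindowVariance:
    def test_constant_series_zero_variance(self):
        layer = _nn.WindowVariance(5)
        v = layer.forward(np.full((1, 2, 20), 3.3))
        np.testing.assert_allclose(v, 0.0, atol=1e-20)

    def test_population_variance_divisor(self):
        layer = _nn.WindowVariance(2)
        v = layer.forward(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4))
        np.testing.assert_allclose(v.ravel(), [0.25, 0.25])

    def test_window_count_and_remainder_discard(self, rng):
        layer = _nn.WindowVariance(25)
        assert layer.forward(rng.normal(size=(1, 2, 800))).shape == (1, 2, 32)
        assert layer.forward(rng.normal(size=(1, 2, 60))).shape == (1, 2, 2)

    def test_variances_are_non_negative(self, rng):
        v = _nn.WindowVariance(7).forward(rng.normal(size=(3, 4, 50)))
        assert v.min() >= 0.0

    def test_window_too_long_rejected(self):
        with pytest.raises(ValueError):
            _nn.WindowVariance(100).forward(np.zeros((1, 1, 50)))


class TestTemporalAttention:
    def test_constant_rows_give_window_mean(self, rng):
        layer = _nn.TemporalAttention(2, n_windows=4, m=4, rng=rng)
        layer.U.value[...] = 5.0  # softmax of a constant row is uniform
        v = rng.normal(size=(3, 4, 4))
        np.testing.assert_allclose(layer.forward(v), v.mean(axis=2), atol=1e-12)

    def test_constant_variances_are_invariant(self, rng):
        layer = _nn.TemporalAttention(2, n_windows=3, m=4, rng=rng)
        v = np.tile(np.array([2.0, 3.0, 4.0, 5.0])[None, :, None], (2, 1, 3))
        np.testing.assert_allclose(layer.forward(v), v[:, :, 0], atol=1e-12)

    def test_hand_oracle_m4_h2_n3(self):
        layer = _nn.TemporalAttention(2, n_windows=3, m=4)
        U = np.array([[0.0, 1.0, 2.0], [1.0, 1.0, 1.0]])
        layer.U.value[...] = U
        v = np.arange(12, dtype=float).reshape(1, 4, 3)
        A = np.exp(U) / np.exp(U).sum(axis=1, keepdims=True)
        expected = np.array(
            [sum(A[c % 2, q] * v[0, c, q] for q in range(3)) for c in range(4)]
        )
        np.testing.assert_allclose(layer.forward(v)[0], expected, atol=1e-12)

    def test_raw_weight_mode_skips_softmax(self):
        layer = _nn.TemporalAttention(1, n_windows=2, m=2, apply_softmax=False)
        layer.U.value[...] = np.array([[2.0, -1.0]])
        v = np.ones((1, 2, 2))
        np.testing.assert_allclose(layer.forward(v).ravel(), [1.0, 1.0])

    def test_group_size_must_divide(self):
        with pytest.raises(ValueError):
            _nn.TemporalAttention(3, n_windows=2, m=4)


class TestFullForward:
    def test_probabilities_on_simplex(self, tiny_config, rng):
        net = DCAMNet(tiny_config, seed=0)
        p = net.predict_proba(rng.normal(size=(6, 4, 3, 50)))
        assert p.min() >= 0.0
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_samples_identical_rows(self, tiny_config, rng):
        net = DCAMNet(tiny_config, seed=0)
        x = np.tile(rng.normal(size=(1, 4, 3, 50)), (5, 1, 1, 1))
        p = net.predict_proba(x)
        np.testing.assert_allclose(p, np.broadcast_to(p[0], p.shape), atol=1e-12)

    def test_batch_permutation_equivariance(self, tiny_config, rng):
        net = DCAMNet(tiny_config, seed=0)
        x = rng.normal(size=(6, 4, 3, 50))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            net.predict_proba(x)[perm], net.predict_proba(x[perm]), atol=1e-10
        )

    def test_shape_mismatch_rejected(self, tiny_config, rng):
        net = DCAMNet(tiny_config, seed=0)
        with pytest.raises(ValueError):
            net.forward(rng.normal(size=(2, 4, 3, 49)))


class TestGradients:
    def test_finite_difference_check_all_variants(self, tiny_config, rng):
        """Analytic backprop agrees with central differences for every variant."""
        x = rng.normal(size=(5, 4, 3, 50))
        y = rng.integers(0, 2, 5)
        for variant in ("full", "static_K1", "no_spatial", "no_temporal", "minimal"):
            net = DCAMNet(tiny_config, variant=variant, seed=1)
            for p in net.params():
                p.grad[...] = 0.0
            logits = net.forward(x, train=True)
            _, _, dl = _nn.softmax_cross_entropy(logits, y)
            net.backward(dl)
            eps = 1e-6
            for p in net.params():
                flat = p.value.ravel()
                for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                    old = flat[i]
                    flat[i] = old + eps
                    lp = _nn.softmax_cross_entropy(net.forward(x, train=True), y)[0]
                    flat[i] = old - eps
                    lm = _nn.softmax_cross_entropy(net.forward(x, train=True), y)[0]
                    flat[i] = old
                    num = (lp - lm) / (2 * eps)
                    ana = p.grad.ravel()[i]
                    assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), (variant, p.name)
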