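"""Unit tests of the autodiff engine: every primitive is checked against
finite differences, and convolution/resampling against independent oracles
(scipy.signal correlation, closed-form bilinear weights)."""

import numpy as np
import pytest
from scipy.signal import correlate

from rggcunet import nn
from rggcunet.nn import functional as F
from rggcunet.nn.tensor import Tensor, concat
from conftest import finite_difference_check


def _t(rng, shape, scale=1.0):
    return Tensor(rng.normal(size=shape) * scale, requires_grad=True)


class TestGradients:
    @pytest.mark.parametrize("name,builder", [
        ("conv_dense", lambda x, rng: (
            lambda w=_t(rng, (4, 3, 3, 3), 0.4), b=_t(rng, (4,)):
            (lambda: F.conv2d(x, w, b, stride=1, padding=1), [x, w, b]))()),
        ("conv_stride2", lambda x, rng: (
            lambda w=_t(rng, (4, 3, 3, 3), 0.4), b=_t(rng, (4,)):
            (lambda: F.conv2d(x, w, b, stride=2, padding=1), [x, w, b]))()),
        ("conv_1x1", lambda x, rng: (
            lambda w=_t(rng, (5, 3, 1, 1)):
            (lambda: F.conv2d(x, w), [x, w]))()),
        ("conv_depthwise", lambda x, rng: (
            lambda w=_t(rng, (3, 1, 3, 3)):
            (lambda: F.conv2d(x, w, stride=2, padding=1, groups=3), [x, w]))()),
        ("conv_transpose", lambda x, rng: (
            lambda w=_t(rng, (3, 4, 2, 2)), b=_t(rng, (4,)):
            (lambda: F.conv_transpose2d(x, w, b, stride=2), [x, w, b]))()),
        ("max_pool", lambda x, rng: (lambda: F.max_pool2d(x, 3, 2, 1), [x])),
        ("bilinear", lambda x, rng: (lambda: F.bilinear_resize(x, 13, 9), [x])),
        ("softmax", lambda x, rng: (lambda: F.softmax(x, 1), [x])),
        ("mean_axis", lambda x, rng: (
            lambda: x.mean(axis=3, keepdims=True), [x])),
        ("sigmoid_mul", lambda x, rng: (
            lambda: x.sigmoid() * x, [x])),
        ("concat_slice", lambda x, rng: (
            lambda: concat([x, x * 2.0], axis=1)[:, 2:5], [x])),
    ])
    def test_matches_finite_differences(self, rng, name, builder):
        x = _t(rng, (2, 3, 6, 6))
        fn, tensors = builder(x, rng)
        finite_difference_check(fn, tensors, rng)

    def test_batch_norm_training_and_eval(self, rng):
        x = _t(rng, (2, 3, 6, 6))
        gamma = _t(rng, (3,))
        beta = _t(rng, (3,))
        rm, rv = np.zeros(3), np.ones(3)
        finite_difference_check(
            lambda: F.batch_norm2d(x, gamma, beta, rm.copy(), rv.copy(),
                                   training=True),
            [x, gamma, beta], rng, tol=1e-3)
        finite_difference_check(
            lambda: F.batch_norm2d(x, gamma, beta, rm, rv, training=False),
            [x, gamma, beta], rng)


class TestConvOracle:
    @pytest.mark.parametrize("stride,padding", [(1, 1), (2, 1), (1, 0)])
    def test_dense_conv_matches_scipy_correlation(self, rng, stride, padding):
        x = rng.normal(size=(1, 3, 8, 8))
        w = rng.normal(size=(2, 3, 3, 3))
        mine = F.conv2d(Tensor(x), Tensor(w), stride=stride,
                        padding=padding).data
        xp = np.pad(x, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
        for o in range(2):
            ref = sum(correlate(xp[0, c], w[o, c], mode="valid")
                      for c in range(3))[::stride, ::stride]
            np.testing.assert_allclose(mine[0, o], ref, atol=1e-12)

    def test_depthwise_matches_per_channel_correlation(self, rng):
        x = rng.normal(size=(1, 4, 6, 6))
        w = rng.normal(size=(4, 1, 3, 3))
        mine = F.conv2d(Tensor(x), Tensor(w), padding=1, groups=4).data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        for c in range(4):
            ref = correlate(xp[0, c], w[c, 0], mode="valid")
            np.testing.assert_allclose(mine[0, c], ref, atol=1e-12)

    def test_transpose_conv_tiles_kernel(self, rng):
        # with kernel == stride each input pixel paints one k x k tile
        x = np.zeros((1, 1, 3, 3))
        x[0, 0, 1, 2] = 2.0
        w = rng.normal(size=(1, 1, 2, 2))
        y = F.conv_transpose2d(Tensor(x), Tensor(w), stride=2).data
        expected = np.zeros((1, 1, 6, 6))
        expected[0, 0, 2:4, 4:6] = 2.0 * w[0, 0]
        np.testing.assert_allclose(y, expected, atol=1e-14)


class TestBilinearOracle:
    def test_2x2_to_4x4_closed_form(self):
        """Half-pixel-centre doubling: sample coords (-.25,.25,.75,1.25)
        clip to [0,1], giving per-axis weights (1,0),(3/4,1/4),(1/4,3/4),(0,1)."""
        a, b, c, d = 1.0, 3.0, 5.0, 11.0
        x = Tensor(np.array(\
            [[[[a, b], [c, d]]]]))
        got = F.bilinear_resize(x, 4, 4).data[0, 0]
        wts = [(1.0, 0.0), (0.75, 0.25), (0.25, 0.75), (0.0, 1.0)]
        expected = np.empty((4, 4))
        for i, (wi0, wi1) in enumerate(wts):
            for j, (wj0, wj1) in enumerate(wts):
                expected[i, j] = (wi0 * wj0 * a + wi0 * wj1 * b
                                  + wi1 * wj0 * c + wi1 * wj1 * d)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_constant_map_stays_constant(self):
        x = Tensor(np.full((1, 2, 3, 5), 0.7))
        y = F.bilinear_resize(x, 9, 10).data
        np.testing.assert_allclose(y, 0.7, atol=1e-12)


class TestOptim:
    def test_adam_zero_lr_leaves_parameters_unchanged(self, rng):
        layer = nn.Conv2d(3, 4, 3, padding=1)
        before = {n: p.data.copy() for n, p in layer.named_parameters()}
        opt = nn.Adam(layer.parameters(), lr=0.0)
        for _ in range(3):
            out = layer(Tensor(rng.normal(size=(2, 3, 5, 5)).astype(np.float32)))
            layer.zero_grad()
            (out * out).sum().backward()
            opt.step()
        for n, p in layer.named_parameters():
            np.testing.assert_array_equal(p.data, before[n])

    def test_adam_decreases_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            (p * p).sum().backward()
            opt.step()
        assert np.abs(p.data).max() < 0.5

    def test_state_dict_roundtrip(self, rng):
        a = nn.Sequential(nn.Conv2d(3, 4, 3, padding=1), nn.BatchNorm2d(4))
        b = nn.Sequential(nn.Conv2d(3, 4, 3, padding=1), nn.BatchNorm2d(4))
        x = Tensor(rng.normal(size=(2, 3, 5, 5)).astype(np.float32))
        a.train()(x)  # populate running stats
        b.load_state_dict(a.state_dict())
        a.eval(), b.eval()
        np.testing.assert_array_equal(a(x).data, b(x).data)
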