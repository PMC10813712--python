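"""Block-level tests: ghost block against a nested-loop convolution oracle,
GCA pooling/range/equivariance properties, GGC branch fusion, and RGGC
residual behaviour."""

import numpy as np
import pytest

from rggcunet import nn
from rggcunet.blocks import (AttentionPair, ConfigurationError, GCA,
                             GCAConfig, GGCBlock, GhostBlock, GhostConfig,
                             RGGCBlock, RGGCConfig)
from rggcunet.nn.tensor import Tensor


def loop_conv2d(x, w, b=None, stride=1, padding=0, groups=1):
    """Nested-loop 2D cross-correlation oracle (independent of the engine)."""
    N, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    y = np.zeros((N, O, Ho, Wo))
    opg = O // groups
    for n in range(N):
        for o in range(O):
            g = o // opg
            for i in range(Ho):
                for j in range(Wo):
                    acc = 0.0
                    for cg in range(Cg):
                        c = g * Cg + cg
                        for a in range(kh):
                            for bb in range(kw):
                                acc += xp[n, c, i * stride + a,
                                          j * stride + bb] * w[o, cg, a, bb]
                    y[n, o, i, j] = acc + (b[o] if b is not None else 0.0)
    return y


def _zero_all(module):
    for _, p in module.named_parameters():
        p.data[...] = 0.0


class TestGhostBlock:
    def test_output_channels_and_concat_order(self, rng):
        blk = GhostBlock(16, GhostConfig(32, use_norm_act=False))
        x = Tensor(rng.normal(size=(1, 16, 8, 8)))
        y = blk(x).data
        assert y.shape == (1, 32, 8, 8)
        # channels 0..15 are the pointwise (intrinsic) branch
        intrinsic = loop_conv2d(x.data, blk.primary.weight.data,
                                blk.primary.bias.data)
        np.testing.assert_allclose(y[:, :16], intrinsic, rtol=0, atol=1e-5)
        # channels 16..31 are the depthwise transform of the intrinsic maps
        cheap = loop_conv2d(intrinsic, blk.cheap.weight.data,
                            blk.cheap.bias.data, padding=1, groups=16)
        np.testing.assert_allclose(y[:, 16:], cheap, rtol=0, atol=1e-5)

    def test_matches_loop_oracle_on_tiny_input(self, rng):
        blk = GhostBlock(1, GhostConfig(4, ratio=2, dw_kernel=3,
                                        use_norm_act=False))
        x = rng.normal(size=(1, 1, 4, 4))
        y = blk(Tensor(x)).data
        intrinsic = loop_conv2d(x, blk.primary.weight.data,
                                blk.primary.bias.data)
        cheap = loop_conv2d(intrinsic, blk.cheap.weight.data,
                            blk.cheap.bias.data, padding=1, groups=2)
        np.testing.assert_allclose(y, np.concatenate([intrinsic, cheap], 1),
                                   atol=1e-5)

    def test_zeroed_weights_give_zero_output(self, rng):
        for use_norm in (False, True):
            blk = GhostBlock(3, GhostConfig(8, use_norm_act=use_norm))
            _zero_all(blk)
            y = blk(Tensor(rng.normal(size=(2, 3, 5, 5)))).data
            np.testing.assert_array_equal(y, 0.0)

    def test_stride_two_halves_spatial_dims(self, rng):
        blk = GhostBlock(4, GhostConfig(8), stride=2)
        assert blk(Tensor(rng.normal(size=(1, 4, 8, 8)))).shape == (1, 8, 4, 4)

    def test_fewer_parameters_than_dense_conv(self):
        cin = cout = 64
        ghost = GhostBlock(cin, GhostConfig(cout))
        dense = nn.Sequential(nn.Conv2d(cin, cout, 3, padding=1, bias=False),
                              nn.BatchNorm2d(cout))
        n_ghost = sum(p.size for p in ghost.parameters())
        n_dense = sum(p.size for p in dense.parameters())
        assert n_ghost < n_dense

    @pytest.mark.parametrize("bad", [
        lambda: GhostConfig(31, ratio=2),
        lambda: GhostConfig(32, dw_kernel=4),
        lambda: GhostConfig(32, ratio=1),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            bad()


class TestGCA:
    def test_pooled_descriptors_match_loop_mean(self, rng):
        x = rng.normal(size=(1, 2, 3, 4))
        z_h, z_w = GCA.pool(Tensor(x))
        for c in range(2):
            for i in range(3):
                assert abs(z_h.data[0, c, i, 0]
                           - sum(x[0, c, i, j] for j in range(4)) / 4) < 1e-6
            for j in range(4):
                assert abs(z_w.data[0, c, 0, j]
                           - sum(x[0, c, i, j] for i in range(3)) / 3) < 1e-6

    def test_attention_strictly_inside_unit_interval(self, rng):
        gca = GCA(GCAConfig(8, 12))
        pair = gca(Tensor(rng.normal(size=(2, 8, 6, 5))))
        assert isinstance(pair, AttentionPair)
        assert pair.a_h.shape == (2, 12, 6, 1)
        assert pair.a_w.shape == (2, 12, 1, 5)
        for a in pair:
            assert (a.data > 0).all() and (a.data < 1).all()

    def test_constant_input_gives_directionally_constant_attention(self):
        gca = GCA(GCAConfig(4, 6)).eval()
        pair = gca(Tensor(np.full((1, 4, 7, 5), 0.3)))
        np.testing.assert_allclose(
            pair.a_h.data,
            np.broadcast_to(pair.a_h.data[:, :, :1, :], pair.a_h.shape),
            atol=1e-6)
        np.testing.assert_allclose(
            pair.a_w.data,
            np.broadcast_to(pair.a_w.data[:, :, :, :1], pair.a_w.shape),
            atol=1e-6)

    def test_row_permutation_equivariance_of_height_path(self, rng):
        gca = GCA(GCAConfig(4, 6)).eval()
        x = rng.normal(size=(1, 4, 6, 5))
        perm = rng.permutation(6)
        a1 = gca(Tensor(x)).a_h.data
        a2 = gca(Tensor(x[:, :, perm, :])).a_h.data
        np.testing.assert_allclose(a2, a1[:, :, perm, :], atol=1e-6)


class TestGGCBlock:
    def test_output_is_product_of_independent_branch_outputs(self, rng):
        blk = GGCBlock(8, 12).eval()
        x = Tensor(rng.normal(size=(1, 8, 6, 6)))
        y = blk(x).data
        ghost = blk.ghost(x).data
        a_h, a_w = blk.gca(x)
        np.testing.assert_allclose(y, ghost * a_h.data * a_w.data, atol=1e-6)

    def test_all_ones_attention_reduces_to_ghost_branch(self, rng, monkeypatch):
        blk = GGCBlock(8, 12).eval()
        x = Tensor(rng.normal(size=(1, 8, 6, 6)))
        ghost = blk.ghost(x).data
        monkeypatch.setattr(blk, "gca", lambda t: AttentionPair(
            Tensor(np.ones((1, 12, 6, 1))), Tensor(np.ones((1, 12, 1, 6)))))
        np.testing.assert_array_equal(blk(x).data, ghost)

    def test_attention_only_attenuates(self, rng):
        blk = GGCBlock(8, 12).eval()
        x = Tensor(rng.normal(size=(1, 8, 6, 6)))
        assert (np.abs(blk(x).data) <= np.abs(blk.ghost(x).data) + 1e-12).all()


class TestRGGCBlock:
    def test_zeroed_main_path_is_exact_identity(self, rng):
        blk = RGGCBlock(RGGCConfig(8, 16, 8, stride=1))
        for name, p in blk.named_parameters():
            if not name.startswith("shortcut"):
                p.data[...] = 0.0
        blk.eval()
        x = rng.normal(size=(2, 8, 6, 6))
        np.testing.assert_array_equal(blk(Tensor(x)).data, x)

    def test_stride_two_downsamples(self, rng):
        blk = RGGCBlock(RGGCConfig(4, 12, 10, stride=2))
        y = blk(Tensor(rng.normal(size=(1, 4, 32, 32)).astype(np.float32)))
        assert y.shape == (1, 10, 16, 16)

    def test_every_parameter_group_receives_gradient(self, rng):
        blk = RGGCBlock(RGGCConfig(4, 8, 6, stride=2))
        x = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        out = blk(x)
        blk.zero_grad()
        (out * out).sum().backward()
        for name, p in blk.named_parameters():
            assert p.grad is not None, f"{name} got no gradient"
            assert np.abs(p.grad).sum() > 0, f"{name} gradient is zero"

    def test_invalid_stride_rejected(self):
        with pytest.raises(ConfigurationError):
            RGGCConfig(4, 8, 6, stride=3)

    def test_deterministic_in_eval_mode(self, rng):
        blk = RGGCBlock(RGGCConfig(4, 8, 6)).eval()
        x = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(blk(x).data, blk(x).data)
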