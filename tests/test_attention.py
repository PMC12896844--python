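"""Oracle and invariant tests for the CBAM and selective-kernel operators."""

import numpy as np
import pytest

from ccw.attention import CBAM, ChannelAttention, SKAttention, SpatialAttention
from ccw.autodiff import Tensor

from conftest import randomize_bn1d, randomize_bn2d
from oracles import (cbam_loop, channel_attention_loop, sigmoid,
                     sk_attention_loop, spatial_attention_loop)


def _sk_params(sk: SKAttention) -> dict:
    return {
        "branch_w": [b.weight.data for b in sk.branches],
        "branch_b": [b.bias.data for b in sk.branches],
        "bn_gamma": [bn.gamma.data for bn in sk.branch_bns],
        "bn_beta": [bn.beta.data for bn in sk.branch_bns],
        "bn_rm": [bn.running_mean for bn in sk.branch_bns],
        "bn_rv": [bn.running_var for bn in sk.branch_bns],
        "fuse_w": sk.fuse_fc.weight.data,
        "fuse_gamma": sk.fuse_bn.gamma.data,
        "fuse_beta": sk.fuse_bn.beta.data,
        "fuse_rm": sk.fuse_bn.running_mean,
        "fuse_rv": sk.fuse_bn.running_var,
        "sel_w": [fc.weight.data for fc in sk.select_fc],
        "sel_b": [fc.bias.data for fc in sk.select_fc],
    }


class TestChannelAttention:
    def test_constant_map_collapses_pools(self, rng):
        """Spatially constant channels make avg == max, so Mc = sigma(2 MLP(v))."""
        c = 4
        ca = ChannelAttention(c, reduction=2, rng=rng)
        v = rng.normal(size=c)
        f = Tensor(np.broadcast_to(v[None, :, None, None], (1, c, 3, 3)).copy())
        got = ca(f).data[0]
        mlp = ca.fc1.weight.data @ np.maximum(ca.fc0.weight.data @ v, 0)
        np.testing.assert_allclose(got, sigmoid(2 * mlp), atol=1e-12)

    def test_zero_weights_give_half(self, rng):
        ca = ChannelAttention(4, reduction=2, rng=rng)
        ca.fc0.weight.data[:] = 0
        ca.fc1.weight.data[:] = 0
        f = Tensor(rng.normal(size=(2, 4, 3, 3)))
        np.testing.assert_allclose(ca(f).data, 0.5, atol=1e-15)

    def test_reduction_must_divide_channels(self, rng):
        with pytest.raises(ValueError, match="divide"):
            ChannelAttention(6, reduction=4, rng=rng)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(13)
        ca = ChannelAttention(4, reduction=2, rng=rng)
        f = rng.normal(size=(4, 3, 3))
        got = ca(Tensor(f[None])).data[0]
        want = channel_attention_loop(f, ca.fc0.weight.data, ca.fc1.weight.data)
        np.testing.assert_allclose(got, want, atol=1e-6)


class TestSpatialAttention:
    def test_zero_kernel_gives_half(self, rng):
        sa = SpatialAttention(rng)
        sa.conv.weight.data[:] = 0
        f = Tensor(rng.normal(size=(1, 3, 8, 8)))
        np.testing.assert_allclose(sa(f).data, 0.5, atol=1e-15)

    def test_constant_input_constant_interior(self, rng):
        """Away from the zero-padded border a constant map yields a constant gate."""
        sa = SpatialAttention(rng)
        f = Tensor(np.full((1, 2, 16, 16), 1.7))
        out = sa(f).data[0, 0]
        interior = out[3:-3, 3:-3]
        np.testing.assert_allclose(interior, interior[0, 0], atol=1e-12)

    def test_rejects_non_7x7(self, rng):
        with pytest.raises(ValueError, match="7"):
            SpatialAttention(rng, kernel=5)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(14)
        sa = SpatialAttention(rng)
        f = rng.normal(size=(3, 6, 6))
        got = sa(Tensor(f[None])).data[0, 0]
        want = spatial_attention_loop(f, sa.conv.weight.data)
        np.testing.assert_allclose(got, want, atol=1e-6)


class TestCBAM:
    def test_zero_input_zero_output(self, rng):
        cbam = CBAM(4, rng, reduction=2)
        out = cbam(Tensor(np.zeros((1, 4, 5, 5))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-15)

    def test_never_amplifies(self):
        """Gates lie in (0,1), so |output| <= |input| elementwise."""
        rng = np.random.default_rng(0)
        cbam = CBAM(4, rng, reduction=2)
        for _ in range(100):
            f = rng.normal(size=(1, 4, 5, 5)) * rng.uniform(0.1, 10)
            out = cbam(Tensor(f)).data
            assert (np.abs(out) <= np.abs(f) + 1e-12).all()

    def test_matches_composed_oracle(self):
        rng = np.random.default_rng(29)
        cbam = CBAM(4, rng, reduction=2)
        f = rng.normal(size=(4, 6, 6))
        got = cbam(Tensor(f[None])).data[0]
        want = cbam_loop(f, cbam.channel.fc0.weight.data,
                         cbam.channel.fc1.weight.data,
                         cbam.spatial.conv.weight.data)
        np.testing.assert_allclose(got, want, atol=1e-6)


class TestSKAttention:
    def _make(self, seed, c=4):
        rng = np.random.default_rng(seed)
        sk = SKAttention(c, rng, reduction=2).eval()
        for bn in sk.branch_bns:
            randomize_bn2d(bn, rng)
        randomize_bn1d(sk.fuse_bn, rng)
        return sk

    def test_identical_branches_passthrough(self, rng):
        """If U1 == U2 == U*, then V = U* because a + b = 1."""
        sk = self._make(5)
        b0, b1 = sk.branches
        b1.weight.data[:] = 0
        b0.weight.data[:] = 0
        b0.bias.data[:] = b1.bias.data[:] = 1.0
        for bn in sk.branch_bns:
            bn.running_mean[:] = 0
            bn.running_var[:] = 1 - 1e-5
            bn.gamma.data[:] = 1
            bn.beta.data[:] = 0
        x = Tensor(rng.normal(size=(1, 4, 5, 5)))
        out = sk(x).data
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_equal_logits_average_branches(self, rng):
        """Zero select weights give a = b = 1/2 and V = (U1 + U2) / 2."""
        sk = self._make(6)
        for fc in sk.select_fc:
            fc.weight.data[:] = 0
            fc.bias.data[:] = 0
        x = Tensor(rng.normal(size=(1, 4, 5, 5)))
        us = sk.branch_outputs(x)
        np.testing.assert_allclose(
            sk(x).data, (us[0].data + us[1].data) / 2, atol=1e-12)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        sk = self._make(7)
        x = Tensor(rng.normal(size=(2, 4, 5, 5)))
        ab = sk.select_weights(sk.branch_outputs(x)).data
        assert ab.shape[0] == 2
        np.testing.assert_allclose(ab.sum(axis=0), 1.0, atol=1e-7)
        assert ((ab > 0) & (ab < 1)).all()

    def test_rejects_more_than_two_branches(self, rng):
        with pytest.raises(ValueError, match="two branches"):
            SKAttention(4, rng, kernels=(3, 5, 7))

    def test_matches_loop_oracle(self):
        sk = self._make(41)
        rng = np.random.default_rng(41)
        x = rng.normal(size=(4, 5, 5))
        got = sk(Tensor(x[None])).data[0]
        want, ab = sk_attention_loop(x, _sk_params(sk))
        np.testing.assert_allclose(got, want, atol=1e-6)
        np.testing.assert_allclose(ab.sum(axis=0), 1.0, atol=1e-7)
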