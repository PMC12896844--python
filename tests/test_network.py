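"""Shape contracts, parameter accounting, and block semantics of the network."""

import numpy as np
import pytest

from ccw.autodiff import Tensor
from ccw.network import (NetConfig, RecurrentConvLayer, RRCNNBlock,
                         build_model, predict_mask)

from conftest import randomize_bn2d
from oracles import bn2d_eval_loop, conv2d_loop


def _tiny(depth=3, base=8, **kw):
    kw.setdefault("cbam_reduction", 4)
    kw.setdefault("sk_reduction", 4)
    return NetConfig(depth=depth, base_width=base, n_classes=4,
                     input_size=64, **kw)


class TestRecurrentBlocks:
    def test_t0_is_plain_double_conv_residual(self, rng):
        """t = 0 has no recurrent convolution at all."""
        layer = RecurrentConvLayer(3, 5, t=0, rng=rng)
        assert not hasattr(layer, "conv_rec")
        x = Tensor(rng.normal(size=(1, 3, 6, 6)))
        layer.eval()
        want = np.maximum(layer.bn_ff(layer.conv_ff(x)).data, 0)
        np.testing.assert_allclose(layer(x).data, want, atol=1e-12)

    def test_zero_weights_identity_shortcut(self, rng):
        """All-zero convolutions with an identity shortcut pass x through."""
        block = RRCNNBlock(4, 4, t=1, rng=rng).eval()
        for layer in (block.layer1, block.layer2):
            layer.conv_ff.weight.data[:] = 0
            layer.conv_ff.bias.data[:] = 0
            layer.conv_rec.weight.data[:] = 0
            layer.conv_rec.bias.data[:] = 0
        x = rng.normal(size=(1, 4, 5, 5))
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-12)

    def test_negative_t_rejected(self, rng):
        with pytest.raises(ValueError, match="non-negative"):
            RecurrentConvLayer(3, 4, t=-1, rng=rng)

    def test_t2_matches_unrolled_oracle(self):
        """Two recurrence steps equal a hand-unrolled scalar computation."""
        rng = np.random.default_rng(0)
        layer = RecurrentConvLayer(1, 1, t=2, rng=rng).eval()
        randomize_bn2d(layer.bn_ff, rng)
        randomize_bn2d(layer.bn_rec, rng)
        x = rng.normal(size=(1, 4, 4))

        def bn(v, b):
            return bn2d_eval_loop(v, b.gamma.data, b.beta.data,
                                  b.running_mean, b.running_var)

        a = bn(conv2d_loop(x, layer.conv_ff.weight.data,
                           layer.conv_ff.bias.data), layer.bn_ff)
        h = np.maximum(a, 0)
        for _ in range(2):
            rec = bn(conv2d_loop(h, layer.conv_rec.weight.data,
                                 layer.conv_rec.bias.data), layer.bn_rec)
            h = np.maximum(a + rec, 0)
        got = layer(Tensor(x[None])).data[0]
        np.testing.assert_allclose(got, h, atol=1e-6)


class TestBuildModel:
    @pytest.mark.parametrize("depth,base", [(2, 4), (2, 8), (3, 4), (3, 8)])
    @pytest.mark.parametrize("size", [32, 64])
    def test_shape_contract(self, depth, base, size, rng):
        cfg = NetConfig(depth=depth, base_width=base, n_classes=4,
                        input_size=size, cbam_reduction=4, sk_reduction=4)
        model = build_model(cfg, seed=0).eval()
        x = Tensor(rng.normal(size=(1, 3, size, size)))
        assert model(x).shape == (1, 4, size, size)

    def test_invalid_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(depth=5, input_size=100).validate()

    def test_parameter_count_matches_analytic_sum(self):
        """Framework-reported totals equal the layer-by-layer closed form."""

        def conv_p(i, o, k):
            return o * i * k * k + o

        def bn_p(c):
            return 2 * c

        def rcl_p(i, o, t):
            p = conv_p(i, o, 3) + bn_p(o)
            if t > 0:
                p += conv_p(o, o, 3) + bn_p(o)
            return p

        def block_p(i, o, t):
            p = rcl_p(i, o, t) + rcl_p(o, o, t)
            if i != o:
                p += conv_p(i, o, 1) + bn_p(o)
            return p

        def cbam_p(c, r):
            return 2 * (c // r) * c + 2 * 49        # biasless MLP + 7x7 conv

        def sk_p(c, r):
            d = max(c // r, 4)
            # two branch convs + their BNs, fuse FC (biasless) + BN,
            # two select FCs with bias
            return (conv_p(c, c, 3) + conv_p(c, c, 5) + 2 * bn_p(c)
                    + d * c + bn_p(d) + 2 * (c * d + c))

        def up_p(i, o):
            return i * o * 4 + o

        for depth, base, t in [(2, 4, 2), (3, 8, 1)]:
            cfg = NetConfig(depth=depth, base_width=base, recurrence_t=t,
                            n_classes=4, input_size=32,
                            cbam_reduction=4, sk_reduction=4)
            widths = [base * 2**i for i in range(depth)]
            total = 0
            in_ch = 3
            for w in widths:
                total += block_p(in_ch, w, t) + sk_p(w, 4)
                in_ch = w
            for w in widths[:-1]:
                total += cbam_p(w, 4)
            for i in range(depth - 2, -1, -1):
                total += up_p(widths[i + 1], widths[i])
                total += block_p(2 * widths[i], widths[i], t)
            total += conv_p(widths[0], 4, 1)
            model = build_model(cfg, seed=0)
            assert model.n_parameters() == total

    def test_ablation_parameter_ordering(self):
        """Attention modules only ever add parameters: baseline < +CBAM < +both."""
        base = dict(depth=3, base_width=8, n_classes=4, input_size=64,
                    cbam_reduction=4, sk_reduction=4)
        p0 = build_model(NetConfig(use_cbam=False, use_sk=False, **base)
                         ).n_parameters()
        p1 = build_model(NetConfig(use_cbam=True, use_sk=False, **base)
                         ).n_parameters()
        p2 = build_model(NetConfig(use_cbam=True, use_sk=True, **base)
                         ).n_parameters()
        assert p0 < p1 < p2


class TestPredict:
    def test_deterministic(self, rng):
        model = build_model(_tiny(), seed=4)
        im = rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
        np.testing.assert_array_equal(predict_mask(model, im),
                                      predict_mask(model, im))

    def test_biased_head_gives_all_background(self, rng):
        model = build_model(_tiny(), seed=4)
        model.head.weight.data[:] = 0
        model.head.bias.data[:] = 0
        model.head.bias.data[0] = 10.0
        im = rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
        assert (predict_mask(model, im) == 0).all()

    def test_batch_of_one_equals_single(self, rng):
        """Eval-mode inference is independent of batch packing."""
        model = build_model(_tiny(), seed=2).eval()
        im = rng.random(size=(2, 3, 64, 64))
        both = model(Tensor(im)).data
        one = model(Tensor(im[:1])).data
        np.testing.assert_allclose(both[:1], one, atol=1e-10)

    def test_channel_mismatch_rejected(self, rng):
        model = build_model(_tiny(), seed=0)
        with pytest.raises(ValueError, match="channels"):
            model(Tensor(rng.normal(size=(1, 4, 64, 64))))
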