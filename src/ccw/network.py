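"""Attention-enhanced recurrent-residual U-Net for carcass part segmentation.

The network is a symmetric encoder-decoder.  Each level is a
recurrent-residual block: two recurrent convolutional layers (a feed-forward
3x3 convolution whose output is refined ``t`` times by a recurrent 3x3
convolution) wrapped in a residual shortcut.  Selective-kernel attention can
be appended to every encoder block, and CBAM can gate each skip tensor before
it is concatenated into the decoder.  A 1x1 convolution head emits one logit
per class per pixel.

Production defaults follow the study configuration (depth 5, 64 base
channels, 640x640 inputs); tests and the bundled overfit harness use
desk-scale configurations (depth 3, 8 base channels, 64x64), which exercise
the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat, maxpool2d
from .attention import CBAM, SKAttention
from .layers import BatchNorm2d, Conv2d, ConvTranspose2d, Module


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by ``2**(depth-1)`` so that every
    max-pool halving is exact.
    """

    depth: int = 5
    base_width: int = 64
    recurrence_t: int = 2
    n_classes: int = 4
    in_channels: int = 3
    use_cbam: bool = True
    use_sk: bool = True
    sk_kernels: tuple[int, ...] = (3, 5)
    cbam_reduction: int = 16
    sk_reduction: int = 16
    input_size: int = 640

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.base_width < 1:
            raise ValueError("base_width must be positive")
        if self.recurrence_t < 0:
            raise ValueError("recurrence_t must be non-negative")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.input_size % 2 ** (self.depth - 1) != 0:
            raise ValueError(
                f"input size {self.input_size} not divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sk_kernels"] = list(self.sk_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        if "sk_kernels" in d:
            d["sk_kernels"] = tuple(d["sk_kernels"])
        return cls(**d)


class RecurrentConvLayer(Module):
    """y_0 = relu(BN(conv_ff(x))); y_s = relu(BN(conv_ff(x)) + BN(conv_rec(y_{s-1})))."""

    def __init__(self, in_ch: int, out_ch: int, t: int, rng: np.random.Generator):
        super().__init__()
        if t < 0:
            raise ValueError("recurrence count t must be non-negative")
        self.t = t
        self.conv_ff = Conv2d(in_ch, out_ch, 3, rng)
        self.bn_ff = BatchNorm2d(out_ch)
        if t > 0:
            self.conv_rec = Conv2d(out_ch, out_ch, 3, rng)
            self.bn_rec = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        a = self.bn_ff(self.conv_ff(x))
        h = a.relu()
        for _ in range(self.t):
            h = (a + self.bn_rec(self.conv_rec(h))).relu()
        return h


class RRCNNBlock(Module):
    """Two stacked recurrent conv layers plus a residual shortcut.

    The shortcut is the identity when channel counts match and a 1x1
    convolution (with batch norm) otherwise.
    """

    def __init__(self, in_ch: int, out_ch: int, t: int, rng: np.random.Generator):
        super().__init__()
        self.layer1 = RecurrentConvLayer(in_ch, out_ch, t, rng)
        self.layer2 = RecurrentConvLayer(out_ch, out_ch, t, rng)
        if in_ch != out_ch:
            self.shortcut_conv = Conv2d(in_ch, out_ch, 1, rng)
            self.shortcut_bn = BatchNorm2d(out_ch)
        else:
            self.shortcut_conv = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.layer2(self.layer1(x))
        if self.shortcut_conv is not None:
            return y + self.shortcut_bn(self.shortcut_conv(x))
        return y + x


class AR2UAttnNet(Module):
    """The assembled segmentation network."""

    def __init__(self, config: NetConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        widths = [config.base_width * 2**i for i in range(config.depth)]
        t = config.recurrence_t

        self.enc_blocks = []
        in_ch = config.in_channels
        for w in widths:
            self.enc_blocks.append(RRCNNBlock(in_ch, w, t, rng))
            in_ch = w
        self.sk_blocks = (
            [SKAttention(w, rng, config.sk_kernels, config.sk_reduction)
             for w in widths]
            if config.use_sk else []
        )
        self.cbam_blocks = (
            [CBAM(w, rng, config.cbam_reduction) for w in widths[:-1]]
            if config.use_cbam else []
        )
        self.up_convs = [
            ConvTranspose2d(widths[i + 1], widths[i], rng)
            for i in range(config.depth - 2, -1, -1)
        ]
        self.dec_blocks = [
            RRCNNBlock(2 * widths[i], widths[i], t, rng)
            for i in range(config.depth - 2, -1, -1)
        ]
        self.head = Conv2d(widths[0], config.n_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        if x.shape[1] != cfg.in_channels:
            raise ValueError(
                f"expected {cfg.in_channels} input channels, got {x.shape[1]}"
            )
        skips = []
        h = x
        for i, block in enumerate(self.enc_blocks):
            if i > 0:
                h = maxpool2d(h)
            h = block(h)
            if cfg.use_sk:
                h = self.sk_blocks[i](h)
            if i < cfg.depth - 1:
                skips.append(h)
        for j, (up, dec) in enumerate(zip(self.up_convs, self.dec_blocks)):
            skip = skips[-(j + 1)]
            if cfg.use_cbam:
                skip = self.cbam_blocks[-(j + 1)](skip)
            h = dec(concat([up(h), skip], axis=1))
        return self.head(h)


def build_model(config: NetConfig, seed: int = 0) -> AR2UAttnNet:
    """Construct a seeded, validated network from its configuration."""
    return AR2UAttnNet(config, seed=seed)


def _round_to_multiple(n: int, m: int) -> int:
    return max(m, int(round(n / m)) * m)


def predict_logits(model: AR2UAttnNet, pixels: np.ndarray) -> np.ndarray:
    """Run eval-mode inference on an (H, W, 3) uint8 image; returns (K, H, W)."""
    model.eval()
    h, w = pixels.shape[:2]
    m = 2 ** (model.config.depth - 1)
    if h % m or w % m:
        # resize to the nearest valid size, infer, resize logits back
        from skimage.transform import resize

        hh, ww = _round_to_multiple(h, m), _round_to_multiple(w, m)
        small = resize(pixels.astype(np.float64) / 255.0, (hh, ww), order=1,
                       anti_aliasing=False)
        x = Tensor(small.transpose(2, 0, 1)[None])
        logits = model(x).data[0]
        return resize(logits, (logits.shape[0], h, w), order=1,
                      anti_aliasing=False)
    x = Tensor((pixels.astype(np.float64) / 255.0).transpose(2, 0, 1)[None])
    return model(x).data[0]


def predict_mask(model: AR2UAttnNet, pixels: np.ndarray) -> np.ndarray:
    """Per-pixel argmax segmentation of an (H, W, 3) uint8 image."""
    return np.argmax(predict_logits(model, pixels), axis=0).astype(np.int64)
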