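"""Channel, spatial, and selective-kernel attention operators.

Two attention families are provided as standalone tensor operators:

* **CBAM** — a channel gate followed by a spatial gate.  The channel gate
  pools each channel globally by mean and by max, pushes both descriptors
  through one shared two-layer perceptron, sums, and squashes with a sigmoid:
  ``Mc = sigma(MLP(avgpool(F)) + MLP(maxpool(F)))``.  The spatial gate
  computes per-pixel mean and max over channels, stacks the two maps,
  convolves with a 7x7 kernel and squashes: ``Ms = sigma(f7x7([mean; max]))``.
  Each gate multiplies the feature map it was computed from, so the composed
  module never increases the magnitude of any element.

* **SK (selective kernel)** — a split-fuse-select operator over exactly two
  convolution branches with different kernel sizes (default 3x3 and 5x5).
  The branch outputs are summed (``U = U1 + U2``), globally average-pooled
  per channel (``s_c``), compressed through a fully connected layer with
  batch norm and ReLU (``z = relu(BN(W s))``), expanded into one logit
  vector per branch, and softmax-normalized across branches so the two
  per-channel weights satisfy ``a + b = 1``.  The output is the convex
  combination ``V = a*U1 + b*U2``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d, softmax
from .layers import BatchNorm1d, BatchNorm2d, Conv2d, Linear, Module


class ChannelAttention(Module):
    """Channel gate: sigma(MLP(avgpool) + MLP(maxpool)), shared MLP, no biases."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"reduction {reduction} must divide channel count {channels}"
            )
        hidden = channels // reduction
        self.fc0 = Linear(channels, hidden, rng, bias=False)
        self.fc1 = Linear(hidden, channels, rng, bias=False)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc1(self.fc0(v).relu())

    def forward(self, f: Tensor) -> Tensor:
        """Return per-channel weights of shape (N, C)."""
        n, c = f.shape[0], f.shape[1]
        flat = f.reshape(n, c, -1)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        return (self._mlp(avg) + self._mlp(mx)).sigmoid()


class SpatialAttention(Module):
    """Spatial gate: sigma(conv7x7([channel-mean; channel-max]))."""

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        super().__init__()
        if kernel != 7:
            raise ValueError("spatial attention uses a 7x7 convolution kernel")
        self.conv = Conv2d(2, 1, kernel, rng, bias=False)

    def forward(self, f: Tensor) -> Tensor:
        """Return a spatial map of shape (N, 1, H, W)."""
        avg = f.mean(axis=1, keepdims=True)
        mx = f.max(axis=1, keepdims=True)
        return conv2d(concat([avg, mx], axis=1), self.conv.weight).sigmoid()


class CBAM(Module):
    """Sequential channel-then-spatial gating of a feature map."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(rng)

    def forward(self, f: Tensor) -> Tensor:
        n, c = f.shape[0], f.shape[1]
        mc = self.channel(f).reshape(n, c, 1, 1)
        fp = f * mc
        ms = self.spatial(fp)
        return fp * ms


class SKAttention(Module):
    """Two-branch selective-kernel attention (split-fuse-select)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 kernels: tuple[int, ...] = (3, 5), reduction: int = 16):
        super().__init__()
        if len(kernels) != 2:
            raise ValueError(
                "selective-kernel attention supports exactly two branches; "
                f"got kernels {kernels!r}"
            )
        self.n_branches = len(kernels)
        d = max(channels // reduction, 4)
        self.branches = [Conv2d(channels, channels, k, rng) for k in kernels]
        self.branch_bns = [BatchNorm2d(channels) for _ in kernels]
        self.fuse_fc = Linear(channels, d, rng, bias=False)
        self.fuse_bn = BatchNorm1d(d)
        self.select_fc = [Linear(d, channels, rng) for _ in kernels]

    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        return [
            bn(conv(x)).relu() for conv, bn in zip(self.branches, self.branch_bns)
        ]

    def select_weights(self, us: list[Tensor]) -> Tensor:
        """Per-branch, per-channel softmax weights, shape (B, N, C)."""
        u = us[0] + us[1]
        n, c = u.shape[0], u.shape[1]
        s = u.reshape(n, c, -1).mean(axis=2)          # global average pool, (N, C)
        z = self.fuse_bn(self.fuse_fc(s)).relu()      # compressed descriptor, (N, d)
        logits = concat(
            [fc(z).reshape(1, n, c) for fc in self.select_fc], axis=0
        )
        return softmax(logits, axis=0)

    def forward(self, x: Tensor) -> Tensor:
        us = self.branch_outputs(x)
        ab = self.select_weights(us)          # (2, N, C)
        n, c = x.shape[0], x.shape[1]
        # select branch weights with one-hot masks so gradients reach the softmax
        mask0 = np.zeros((2, 1, 1)); mask0[0] = 1.0
        mask1 = np.zeros((2, 1, 1)); mask1[1] = 1.0
        a = (ab * Tensor(mask0)).sum(axis=0).reshape(n, c, 1, 1)
        b = (ab * Tensor(mask1)).sum(axis=0).reshape(n, c, 1, 1)
        return us[0] * a + us[1] * b
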