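"""Neural-network layers built on the autodiff engine.

Layers follow the familiar module pattern: parameters are ``Tensor`` objects
discoverable via :meth:`Module.parameters`, and batch normalization switches
between per-batch statistics (training) and stored running statistics
(inference) via :meth:`Module.train`/:meth:`Module.eval`.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, conv_transpose2d


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        stack = list(self.__dict__.values())
        for attr in stack:
            if isinstance(attr, Tensor) and getattr(attr, "name", ""):
                if id(attr) not in seen:
                    seen.add(id(attr))
                    params.append(attr)
            elif isinstance(attr, Module):
                for p in attr.parameters():
                    if id(p) not in seen:
                        seen.add(id(p))
                        params.append(p)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        for p in item.parameters():
                            if id(p) not in seen:
                                seen.add(id(p))
                                params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for attr in self.__dict__.values():
            if isinstance(attr, Module):
                mods.extend(attr.modules())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"bn_{i}_mean"] = m.running_mean
                state[f"bn_{i}_var"] = m.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"param_{i}"], dtype=np.float64)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"bn_{i}_mean"], dtype=np.float64)
                m.running_var = np.asarray(state[f"bn_{i}_var"], dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Stride-1 same-padding convolution with odd kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in), name="weight"
        )
        self.bias = Tensor(np.zeros(out_ch), name="bias") if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution (spatial doubling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            he_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4), name="weight"
        )
        self.bias = Tensor(np.zeros(out_ch), name="bias")

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(he_normal(rng, (out_f, in_f), in_f), name="weight")
        self.bias = Tensor(np.zeros(out_f), name="bias") if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose(1, 0)
        return y if self.bias is None else y + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W).

    Training mode normalizes with batch statistics and updates running
    statistics with momentum; eval mode normalizes with the stored running
    statistics, which makes single-sample inference deterministic.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(n_ch), name="gamma")
        self.beta = Tensor(np.zeros(n_ch), name="beta")
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        g = self.gamma.reshape(1, c, 1, 1)
        b = self.beta.reshape(1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(c)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(c)
            )
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - mu) / sd
        return xhat * g + b


class BatchNorm1d(Module):
    """Per-feature batch normalization for (N, F) inputs (SK fuse stage)."""

    def __init__(self, n_f: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(n_f), name="gamma")
        self.beta = Tensor(np.zeros(n_f), name="beta")
        self.running_mean = np.zeros(n_f)
        self.running_var = np.ones(n_f)

    def forward(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data[0]
            )
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - self.running_mean) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
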