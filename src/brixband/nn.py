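"""Small neural-network layers and an Adam optimizer on the autodiff core."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: tracks parameters and sub-modules by attribute name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise KeyError("state dict keys do not match module parameters")
        for name, arr in state.items():
            own[name].data = np.asarray(arr, dtype=np.float64).copy()

    def param_hash(self) -> str:
        """Stable digest of all parameter values (freeze-contract checks)."""
        import hashlib

        h = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(array: np.ndarray) -> Tensor:
    return Tensor(array, requires_grad=True)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _param(_kaiming(rng, (n_in, n_out), n_in))
        self.bias = _param(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        self.padding = kernel // 2 if padding is None else padding
        fan_in = c_in * kernel * kernel
        self.weight = _param(_kaiming(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.bias = _param(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.padding = kernel // 2
        self.weight = _param(_kaiming(rng, (channels, kernel, kernel),
                                      kernel * kernel))
        self.bias = _param(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return ad.depthwise_conv2d(x, self.weight, self.bias,
                                   padding=self.padding)


class EfficientChannelAttention(Module):
    """Channel recalibration via a 1-D convolution over the pooled
    channel descriptor (local cross-channel interaction, no reduction)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 gamma: int = 2, b: int = 1):
        super().__init__()
        k = int(abs((np.log2(channels) + b) / gamma))
        k = max(3, k if k % 2 else k + 1)
        self.kernel_size = k
        self.weight = _param(rng.normal(0.0, 1.0 / np.sqrt(k), size=k))

    def forward(self, x: Tensor) -> Tensor:
        desc = x.mean(axis=(2, 3))                      # (N, C)
        w = ad.sigmoid(ad.conv1d(desc, self.weight,
                                 padding=self.kernel_size // 2))
        n, c = w.shape
        return x * w.reshape(n, c, 1, 1)


class GeMPool(Module):
    """Generalized-mean pooling with a trainable exponent p.

    p = 1 reproduces average pooling; large p approaches max pooling.
    """

    def __init__(self, p_init: float = 3.0, eps: float = 1e-6):
        super().__init__()
        self.p = _param(np.array(p_init))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        # clamp to >= eps so x**p = exp(p log x) is well defined
        xc = ad.relu(x - self.eps) + self.eps
        powed = ad.exp(self.p * ad.log(xc))
        pooled = powed.mean(axis=(2, 3))                # (N, C)
        return ad.exp(ad.log(pooled) * (1.0 / self.p))


class Adam:
    """Adam with decoupled weight decay and frozen-parameter skipping.

    Weight decay shrinks large single-feature weights, which matters here:
    with spectrally redundant inputs it makes spreading weight across
    correlated bands strictly cheaper than relying on one band, turning
    the use-many-bands direction into a first-order descent direction.
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
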