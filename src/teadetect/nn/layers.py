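"""Module system: parameter containers and the standard trainable layers."""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ConvBNSiLU",
    "MaxPool2d",
    "Identity",
]


class Module:
    """Base class: walks attributes to find parameters and submodules."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict, strict: bool = True):
        own = dict(self.named_parameters())
        for name, arr in state.items():
            if name not in own:
                if strict:
                    raise KeyError(f"unexpected parameter {name!r}")
                continue
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            own[name].data[...] = arr

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, str(i), m)

    def __iter__(self):
        i = 0
        while hasattr(self, str(i)):
            yield getattr(self, str(i))
            i += 1

    def __getitem__(self, i):
        return getattr(self, str(i))

    def __len__(self):
        return sum(1 for _ in self)

    def append(self, m: Module):
        setattr(self, str(len(self)), m)


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """Plain convolution; bias optional (off when followed by batch norm)."""

    def __init__(self, c_in, c_out, kernel=1, stride=1, bias=True, pad=None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(
            _kaiming_uniform(rng, (c_out, c_in, kernel, kernel), fan_in),
            requires_grad=True,
        )
        self.bias = (
            Tensor(_kaiming_uniform(rng, (c_out,), fan_in), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W); eps matches detector convention."""

    def __init__(self, channels, eps=1e-3, momentum=0.03):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) / (var + self.eps) ** 0.5
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class Linear(Module):
    def __init__(self, c_in, c_out, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(
            _kaiming_uniform(rng, (c_in, c_out), c_in), requires_grad=True
        )
        self.bias = Tensor(
            _kaiming_uniform(rng, (c_out,), c_in), requires_grad=True
        )

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvBNSiLU(Module):
    """CBS block: convolution -> batch norm -> SiLU, same padding."""

    def __init__(self, c_in, c_out, kernel=1, stride=1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, kernel, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class MaxPool2d(Module):
    def __init__(self, kernel=5, stride=1, pad=None):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2 if pad is None else pad

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel, self.stride, self.pad)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class SGD:
    """SGD with classical momentum and decoupled-from-BN weight decay."""

    def __init__(self, params, lr=0.01, momentum=0.937, weight_decay=0.0005):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:  # skip BN/bias vectors
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
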