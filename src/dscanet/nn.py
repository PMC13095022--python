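"""Neural-network layers, parameter containers and optimizers.

Thin module system over :mod:`dscanet.autodiff`: layers hold named
:class:`Parameter` tensors, compose through ``__call__``, and support
state-dict round-trips for checkpointing.  Includes the Adam optimizer
and a reduce-on-plateau learning-rate schedule used by the training
pipeline.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameter", "Module", "Sequential", "Identity", "Linear", "Conv2d",
    "LayerNorm", "BatchNorm2d", "ReLU", "GELU", "Sigmoid", "DepthwiseConv1d",
    "ConvBNReLU", "Adam", "SGD", "ReduceLROnPlateau", "seeded_rng",
]


def seeded_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed) % (2 ** 31))


class Parameter(Tensor):
    """A tensor that is always trainable."""

    def __init__(self, data, name: str | None = None):
        super().__init__(data, requires_grad=True, name=name)
        self.requires_grad = True  # independent of the grad-enabled flag


class Module:
    """Base class: attribute-registered parameters and submodules."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, key, value):
        if isinstance(value, Parameter):
            self._params[key] = value
        elif isinstance(value, Module):
            self._modules[key] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{key}.{i}"] = v
        object.__setattr__(self, key, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield (f"{prefix}{k}", p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{k}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        """Total trainable parameter elements."""
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> dict:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for k in getattr(self, "_buffers", ()):
            yield (f"{prefix}{k}", getattr(self, k))
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix=f"{prefix}{k}.")

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in state.items():
            if k in own:
                if own[k].shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}: {own[k].shape} vs {v.shape}")
                own[k].data = np.asarray(v, dtype=own[k].dtype)
            elif k in bufs:
                bufs[k][...] = v
            else:
                raise KeyError(f"unexpected key in state dict: {k}")
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]}")


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class GELU(Module):
    def forward(self, x):
        return ad.gelu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


def _kaiming(rng, fan_in: int, shape) -> np.ndarray:
    std = math.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


def _trunc_normal(rng, shape, std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng, bias: bool = True):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.weight = Parameter(_trunc_normal(rng, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng, stride: int = 1,
                 padding: int | None = None, groups: int = 1, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = k // 2
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (c_in // groups) * k * k
        self.weight = Parameter(_kaiming(rng, fan_in, (c_out, c_in // groups, k, k)))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)


class DepthwiseConv1d(Module):
    """Depthwise 1-D convolution along the token axis of (B, P, C) input.

    The per-channel "1-D deep convolution" projection used to map token
    sequences: each channel is filtered independently with its own
    length-``k`` kernel (zero padding, stride 1).
    """

    def __init__(self, channels: int, k: int, rng):
        super().__init__()
        self.k = k
        self.weight = Parameter(_trunc_normal(rng, (channels, 1, 1, k), std=1.0 / math.sqrt(k)))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x):
        B, P, C = x.shape
        # run as a grouped 2-D conv over a (B, C, 1, P) view
        xi = x.transpose(0, 2, 1).reshape(B, C, 1, P)
        if self.k > 1:
            xi = ad.pad2d(xi, (0, 0, self.k // 2, self.k - 1 - self.k // 2))
        y = ad.conv2d(xi, self.weight, self.bias, padding=0, groups=C)
        return y.reshape(B, C, P).transpose(0, 2, 1)


class LayerNorm(Module):
    """Normalization over the trailing feature axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        object.__setattr__(self, "_buffers", ("running_mean", "running_var"))

    def forward(self, x):
        if self.training and ad.is_grad_enabled():
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xc = x - mu
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class ConvBNReLU(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng, stride: int = 1, groups: int = 1):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, rng, stride=stride, groups=groups, bias=False)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x):
        return ad.relu(self.bn(self.conv(x)))


# -- optimizers ----------------------------------------------------------------

class Adam:
    """Adam with decoupled weight-decay-free L2 applied through the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD:
    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            b *= self.momentum
            b += g
            p.data -= self.lr * b

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer lr after ``patience`` epochs
    without improvement of the monitored quantity (lower is better)."""

    def __init__(self, optimizer, patience: int = 5, factor: float = 0.5,
                 min_lr: float = 1e-6):
        self.optimizer = optimizer
        self.patience, self.factor, self.min_lr = patience, factor, min_lr
        self.best = math.inf
        self.bad_epochs = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, metric: float):
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
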