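"""Minimal neural-network module system on top of :mod:`foveaseg.autodiff`.

Provides the layer types the segmentation network needs (convolutions, batch
norm, activations), parameter registration/serialization, He initialization
and the Adam optimizer.  Mirrors the familiar Module/Parameter idiom so the
architecture code reads conventionally.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_GLOBAL_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> np.random.Generator:
    """Seed the generator used for parameter initialization; returns it."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)
    return _GLOBAL_RNG


def _rng(rng=None) -> np.random.Generator:
    return rng if rng is not None else _GLOBAL_RNG


class Parameter(Tensor):
    """A Tensor that is a trainable leaf of a Module."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_buffers():
            state[name] = m.copy()
        return state

    def _named_buffers(self, prefix: str = ""):
        for name, m in self._modules.items():
            yield from m._named_buffers(prefix=f"{prefix}{name}.")
        for name in getattr(self, "_buffers", ()):  # set by layers that track stats
            yield f"{prefix}{name}", getattr(self, name)

    def load_state_dict(self, state: dict):
        own = {name: p for name, p in self.named_parameters()}
        buffers = {name: (mod, attr) for name, (mod, attr) in self._buffer_owners().items()}
        for key, arr in state.items():
            if key in own:
                if own[key].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}")
                own[key].data = np.asarray(arr, dtype=np.float32)
            elif key in buffers:
                mod, attr = buffers[key]
                object.__setattr__(mod, attr, np.asarray(arr, dtype=np.float32))
            else:
                raise KeyError(f"unexpected key in state dict: {key}")

    def _buffer_owners(self, prefix: str = ""):
        out = {}
        for name, m in self._modules.items():
            out.update(m._buffer_owners(prefix=f"{prefix}{name}."))
        for name in getattr(self, "_buffers", ()):
            out[f"{prefix}{name}"] = (self, name)
        return out

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_init(shape, fan_in, rng) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return _rng(rng).normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Standard 2-D convolution (cross-correlation), zero 'same'/valid padding."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0, bias=True, rng=None):
        super().__init__()
        k = kernel_size
        self.stride, self.padding = stride, padding
        fan_in = in_channels * k * k
        self.weight = Parameter(_he_init((out_channels, in_channels, k, k), fan_in, rng))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    """Per-channel convolution (stride 1), the Ghost 'cheap operation' kernel."""

    def __init__(self, channels, kernel_size, padding=0, bias=True, rng=None):
        super().__init__()
        k = kernel_size
        self.padding = padding
        self.weight = Parameter(_he_init((channels, k, k), k * k, rng))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x):
        return ad.depthwise_conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        object.__setattr__(self, "_buffers", ("running_mean", "running_var"))

    def forward(self, x):
        C = x.shape[1]
        if self.training:
            out, mu, var = ad.batch_norm_train(x, self.weight, self.bias, eps=self.eps)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
            return out
        mu = Tensor(self.running_mean.reshape(1, C, 1, 1))
        var = Tensor(self.running_var.reshape(1, C, 1, 1))
        xhat = (x - mu) / ad.sqrt(var + self.eps)
        w = self.weight.reshape((1, C, 1, 1))
        b = self.bias.reshape((1, C, 1, 1))
        return xhat * w + b


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class Adam:
    """Adam with per-group learning rates (used by the freeze schedule)."""

    def __init__(self, param_groups, betas=(0.9, 0.999), eps=1e-8):
        # param_groups: list of {"params": [...], "lr": float}
        self.groups = [
            {"params": list(g["params"]), "lr": float(g["lr"])} for g in param_groups
        ]
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state = {}

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for group in self.groups:
            lr = group["lr"]
            if lr == 0.0:
                continue
            for p in group["params"]:
                if p.grad is None:
                    continue
                st = self.state.setdefault(id(p), {"m": np.zeros_like(p.data), "v": np.zeros_like(p.data)})
                g = p.grad
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = b2 * st["v"] + (1 - b2) * g * g
                mhat = st["m"] / (1 - b1**self.t)
                vhat = st["v"] / (1 - b2**self.t)
                p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for group in self.groups:
            for p in group["params"]:
                p.grad = None
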