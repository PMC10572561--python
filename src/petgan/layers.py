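"""Neural-network layers built on the autodiff engine.

A deliberately small Module system: layers hold parameter Tensors, expose
``parameters()`` / ``state_dict()`` and a ``training`` flag (batch norm uses
batch statistics while training and running statistics at inference).
Weights are initialized from a zero-mean Gaussian with standard deviation
0.02, the DCGAN convention, using a caller-supplied numpy Generator so that
construction is fully seed-deterministic.
"""

from __future__ import annotations

import numpy as np

from . import engine as E
from .engine import Tensor

DTYPE = np.float32
INIT_STD = 0.02


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self) -> list:
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict:
        state = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                state[key] = v.data
            elif isinstance(v, np.ndarray):
                state[key] = v
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{i}."))
        return state

    def load_state_dict(self, state: dict, prefix: str = "") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                v.data = np.asarray(state[key], dtype=v.data.dtype)
            elif isinstance(v, np.ndarray):
                self.__dict__[name] = np.asarray(state[key], dtype=v.dtype)
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel=4, stride=2, padding=1,
                 bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, INIT_STD, size=(out_ch, in_ch, kernel, kernel))
        self.weight = Tensor(w.astype(DTYPE), requires_grad=True)
        self.bias = (Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)
                     if bias else None)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        y = E.conv2d(x, self.weight, stride=self.stride, padding=self.padding)
        if self.bias is not None:
            y = y + self.bias.reshape((1, -1, 1, 1))
        return y


class ConvTranspose2d(Module):
    def __init__(self, in_ch, out_ch, kernel=4, stride=2, padding=1,
                 bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, INIT_STD, size=(in_ch, out_ch, kernel, kernel))
        self.weight = Tensor(w.astype(DTYPE), requires_grad=True)
        self.bias = (Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)
                     if bias else None)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        k = self.weight.shape[2]
        out_hw = ((h - 1) * self.stride - 2 * self.padding + k,
                  (w - 1) * self.stride - 2 * self.padding + k)
        y = E.conv_transpose2d(x, self.weight, stride=self.stride,
                               padding=self.padding, output_size=out_hw)
        if self.bias is not None:
            y = y + self.bias.reshape((1, -1, 1, 1))
        return y


class BatchNorm2d(Module):
    def __init__(self, n_ch, eps=1e-5, momentum=0.1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.gamma = Tensor(
            rng.normal(1.0, INIT_STD, size=n_ch).astype(DTYPE),
            requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=DTYPE)
        self.running_var = np.ones(n_ch, dtype=DTYPE)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.ravel()).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.ravel()).astype(DTYPE)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape((1, -1, 1, 1)) \
            + self.beta.reshape((1, -1, 1, 1))


class InstanceNorm2d(Module):
    def __init__(self, n_ch, eps=1e-5, affine=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.gamma = (Tensor(rng.normal(1.0, INIT_STD, size=n_ch)
                             .astype(DTYPE), requires_grad=True)
                      if affine else None)
        self.beta = (Tensor(np.zeros(n_ch, dtype=DTYPE), requires_grad=True)
                     if affine else None)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=(2, 3), keepdims=True)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        if self.gamma is not None:
            xhat = xhat * self.gamma.reshape((1, -1, 1, 1)) \
                + self.beta.reshape((1, -1, 1, 1))
        return xhat


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def make_norm(kind: str | None, n_ch, rng):
    if kind in (None, "none"):
        return None
    if kind == "batch":
        return BatchNorm2d(n_ch, rng=rng)
    if kind == "instance":
        return InstanceNorm2d(n_ch, rng=rng)
    raise ValueError(f"unknown norm kind {kind!r}")
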