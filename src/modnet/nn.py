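"""Neural-network layers on top of :mod:`modnet.autograd`.

Layers follow the usual Module contract: named parameters discovered
recursively, an explicit train/eval switch (batch-norm is the only layer
that cares), and seeded initialisation — every layer takes a
``numpy.random.Generator`` so a model is a pure function of its seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d, maxpool2d
from .errors import ConfigurationError

__all__ = [
    "Module", "Sequential", "Identity", "ReLU",
    "Conv2d", "Linear", "BatchNorm2d", "MaxPool2d",
]


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: Tensor) -> Tensor:
        value.requires_grad = True
        self._params[name] = value
        object.__setattr__(self, name, value)
        return value

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        object.__setattr__(self, name, value)
        return value

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield (prefix + n, b)
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix + mn + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({n: b.copy() for n, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = np.array(d[n], dtype=np.float64)
        for n, b in self.named_buffers():
            b[...] = d[n]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ConfigurationError(
                f"groups={groups} must divide in_ch={in_ch} and out_ch={out_ch}")
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_ch // groups) * kernel * kernel
        std = math.sqrt(2.0 / fan_in)  # He init for ReLU nets
        w = rng.normal(0.0, std, size=(out_ch, in_ch // groups, kernel, kernel))
        self.register_parameter("weight", Tensor(w))
        if bias:
            self.register_parameter("bias", Tensor(np.zeros(out_ch)))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding, groups=self.groups)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / in_f)
        self.register_parameter("weight", Tensor(rng.normal(0.0, std, (out_f, in_f))))
        if bias:
            self.register_parameter("bias", Tensor(np.zeros(out_f)))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose((1, 0))
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    """Per-channel normalisation; batch statistics in training mode, running
    statistics at evaluation time (momentum 0.1)."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.register_parameter("gamma", Tensor(np.ones(ch)))
        self.register_parameter("beta", Tensor(np.zeros(ch)))
        self.register_buffer("running_mean", np.zeros(ch))
        self.register_buffer("running_var", np.ones(ch))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var[...] = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel, self.stride, self.padding)
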