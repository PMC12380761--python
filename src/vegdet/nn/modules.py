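"""Lightweight layer/module framework over the autograd core."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor

_GLOBAL_RNG = np.random.default_rng(0)


def seed(n: int) -> None:
    """Seed the initializer RNG used for all newly built layers."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(n)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean[...] = state[f"{name}.running_mean"]
                m.running_var[...] = state[f"{name}.running_var"]

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield (prefix.rstrip("."), self)
        for name, m in self._modules.items():
            yield from m._named_modules(prefix=f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = []
        for m in mods:
            setattr(self, str(len(self._list)), m)
            self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """Bare convolution; He-initialized, bias optional."""

    def __init__(self, cin: int, cout: int, kernel: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1, bias: bool = True):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError(
                f"channels ({cin}->{cout}) not divisible by groups={groups}")
        self.cin, self.cout, self.kernel = cin, cout, kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.groups = groups
        fan_in = cin // groups * kernel * kernel
        w = _GLOBAL_RNG.normal(0.0, np.sqrt(2.0 / fan_in),
                               size=(cout, cin // groups, kernel, kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        return T.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training,
                            momentum=self.momentum, eps=self.eps)


class SiLU(Module):
    def forward(self, x):
        return T.silu(x)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return T.sigmoid(x)


class Upsample(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return T.upsample_nearest(x, self.scale)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int = 1, padding: int | None = None):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x):
        return T.max_pool2d(x, self.kernel, self.stride, self.padding)


class ConvBNAct(Module):
    """Convolution + batch norm + activation, the basic detector building unit."""

    def __init__(self, cin: int, cout: int, kernel: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1,
                 act: str = "silu"):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = {"silu": SiLU, "relu": ReLU, "none": Identity}[act]()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))
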