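"""Neural-network building blocks on top of the autodiff core.

Layers follow the familiar NCHW Module conventions: parameters are
``Tensor``s with ``requires_grad=True``, discovered by attribute walking, and
checkpoints address them by dotted module path.  Initialisation draws from a
package-level RNG so that model construction is reproducible given a seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import core
from .core import Tensor

__all__ = [
    "seed_init",
    "Module",
    "ModuleList",
    "Identity",
    "Conv2d",
    "Linear",
    "InstanceNorm2d",
    "avg_pool2d",
]

_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reset the RNG used for parameter initialisation."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


def _kaiming_uniform(shape, fan_in, rng) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Module:
    """Base class: parameter discovery, state dicts, call protocol."""

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)[:4]} "
                           f"extra={sorted(extra)[:4]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class ModuleList(Module):
    def __init__(self, modules=()):
        self._modules = list(modules)

    def append(self, module: Module) -> None:
        self._modules.append(module)

    def __iter__(self):
        return iter(self._modules)

    def __len__(self):
        return len(self._modules)

    def __getitem__(self, i):
        return self._modules[i]

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._modules):
            yield from m.named_parameters(f"{prefix}{i}.")

    def forward(self, *a, **k):  # pragma: no cover
        raise NotImplementedError("ModuleList is a container")


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """Stride-1 grouped convolution with 'same' zero padding by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int | None = None, groups: int = 1, bias: bool = True):
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"groups={groups} must divide in={in_channels} and out={out_channels}"
            )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = (kernel_size - 1) // 2 if padding is None else padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        shape = (out_channels, in_channels // groups, kernel_size, kernel_size)
        self.weight = Tensor(_kaiming_uniform(shape, fan_in, _INIT_RNG),
                             requires_grad=True)
        self.bias = (Tensor(_kaiming_uniform((out_channels,), fan_in, _INIT_RNG),
                            requires_grad=True) if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.weight, self.bias,
                           padding=self.padding, groups=self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(
            _kaiming_uniform((in_features, out_features), in_features, _INIT_RNG),
            requires_grad=True,
        )
        self.bias = (Tensor(_kaiming_uniform((out_features,), in_features, _INIT_RNG),
                            requires_grad=True) if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        out = core.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial dims."""

    def __init__(self, num_channels: int, eps: float = 1e-5, affine: bool = True):
        self.num_channels = num_channels
        self.eps = eps
        if affine:
            self.weight = Tensor(np.ones((1, num_channels, 1, 1), np.float32),
                                 requires_grad=True)
            self.bias = Tensor(np.zeros((1, num_channels, 1, 1), np.float32),
                               requires_grad=True)
        else:
            self.weight = self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        y = xc * (var + self.eps) ** -0.5
        if self.weight is not None:
            y = y * self.weight + self.bias
        return y


def avg_pool2d(x: Tensor) -> Tensor:
    """2×2 average pooling (spatial dims must be even)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2d needs even spatial dims, got {h}×{w}")
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
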