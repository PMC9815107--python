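"""Layer abstractions over the autograd core.

The surface mirrors the conventions of mainstream deep-learning layer APIs
(modules own parameters and buffers, compose recursively, have train/eval
modes, and serialize through flat ``state_dict`` mappings) so the rest of the
package reads like ordinary model code.

Parameter initialization draws from a ``numpy.random.Generator`` passed to
each constructor; builders thread one seeded generator through the whole
model, making initialization a pure function of the seed.
"""

from __future__ import annotations

from typing import Dict, Iterator, Optional, Tuple

import numpy as np

from .functional import conv2d
from .tensor import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


def _default_rng(rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(0)


class Module:
    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name: str, value) -> None:
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- modes ---------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        for name, p in own.items():
            if name not in state:
                raise KeyError(f"missing parameter in state dict: {name}")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float32).copy()
        # buffers must be written back through their owning module
        for mod, prefix in self._prefixed_modules():
            for bname in mod._buffers:
                key = prefix + bname
                if key in state:
                    mod.register_buffer(bname, state[key].astype(np.float32).copy())

    def _prefixed_modules(self, prefix: str = ""):
        yield self, prefix
        for name, m in self._modules.items():
            yield from m._prefixed_modules(prefix + name + ".")

    # -- call ----------------------------------------------------------
    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        name = str(len(self._items))
        self._items.append(m)
        self._modules[name] = m
        object.__setattr__(self, name, m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.layers:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = _default_rng(rng)
        if in_channels % groups:
            raise ValueError("in_channels must be divisible by groups")
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))  # He init, matches the swish/relu blocks
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels // groups, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding,
            dilation=self.dilation, groups=self.groups,
        )


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        rng = _default_rng(rng)
        bound = float(1.0 / np.sqrt(in_features))
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.register_buffer(
                "running_mean", ((1 - m) * self.running_mean + m * mu.data.reshape(c)).astype(np.float32)
            )
            self.register_buffer(
                "running_var", ((1 - m) * self.running_var + m * var.data.reshape(c)).astype(np.float32)
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Swish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.swish()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()
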