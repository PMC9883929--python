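"""Neural-network modules on top of the autograd engine.

Mirrors the familiar module/parameter idiom: modules own named parameters
and submodules, support state-dict round-trips, and can freeze subtrees for
staged training. Initialization is Kaiming-style for conv/linear weights.
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from .autograd import Tensor, conv2d

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "Sequential",
    "Identity",
]


class Parameter(Tensor):
    def __init__(self, data, requires_grad: bool = True):
        super().__init__(data, requires_grad=requires_grad)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield f"{prefix}{name}", self._buffers[name]
        for name, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{name}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def freeze(self, frozen: bool = True) -> "Module":
        for p in self.parameters():
            p.requires_grad = not frozen
        return self

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self._walk_buffers())
        for key, value in state.items():
            if key in own:
                if own[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                own[key].data = np.asarray(value, dtype=np.float32).copy()
            elif key in bufs:
                holder, short = bufs[key]
                holder._buffers[short] = np.asarray(value).copy()
                object.__setattr__(holder, short, holder._buffers[short])
            else:
                raise KeyError(f"unexpected key {key} in state dict")

    def _walk_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield f"{prefix}{name}", (self, name)
        for name, m in self._modules.items():
            yield from m._walk_buffers(f"{prefix}{name}.")

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: Optional[int] = None,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = (kernel_size - 1) // 2 if padding is None else padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        bound = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(
            rng.normal(0.0, bound, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = (x - mu).pow(2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean
            )
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var
            )
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            rm = self.running_mean.reshape(1, -1, 1, 1)
            rv = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - rm) * (1.0 / np.sqrt(rv + self.eps))
        w = self.weight.reshape(1, self.channels, 1, 1)
        b = self.bias.reshape(1, self.channels, 1, 1)
        return xhat * w + b


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
        zero_init: bool = False,
    ):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._order = []
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
            self._order.append(m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._order:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._order)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
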