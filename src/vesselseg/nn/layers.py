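"""Neural-network building blocks (modules with learnable parameters)."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Parameter", "Conv2d", "BatchNorm2d", "Sequential", "count_parameters"]


class Parameter(Tensor):
    """A tensor that is registered as learnable by its owning module."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: tracks child modules, parameters and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
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
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-learnable persistent state (e.g. batch-norm running stats)."""
        out = {}
        for name in getattr(self, "_buffer_names", ()):
            out[name] = getattr(self, name)
        return out

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, buf in self.buffers().items():
            yield prefix + name, buf
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                params[name].data = np.array(value, dtype=params[name].data.dtype)
            elif name in bufs:
                # buffers are plain arrays on the module; find owner and set
                obj, attr = self._resolve(name)
                setattr(obj, attr, np.array(value))
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _resolve(self, dotted: str):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj._modules[part]
        return obj, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def count_parameters(module: Module) -> int:
    return sum(p.data.size for p in module.parameters())


class Conv2d(Module):
    """2-D convolution layer, Kaiming-initialised (fan-in, ReLU gain)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x,
            self.weight,
            bias=self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
        )


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel.

    Batch statistics during training (with exponential running averages
    kept for inference); running statistics in eval mode.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        object.__setattr__(self, "running_mean", np.zeros(num_features, dtype=np.float64))
        object.__setattr__(self, "running_var", np.ones(num_features, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
            xn = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1).astype(x.dtype)
            sd = np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps).astype(x.dtype)
            xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        gamma = self.gamma.reshape(1, c, 1, 1)
        beta = self.beta.reshape(1, c, 1, 1)
        return xn * gamma + beta


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self._order = []
        for i, mod in enumerate(modules):
            setattr(self, f"m{i}", mod)
            self._order.append(mod)

    def forward(self, x: Tensor) -> Tensor:
        for mod in self._order:
            x = mod(x)
        return x
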