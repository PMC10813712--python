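"""Module/layer abstractions over the functional primitives."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reset the global initialisation RNG (parameter init is then
    deterministic given construction order)."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def _init_rng() -> np.random.Generator:
    return _RNG


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal -------------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix or "(root)", self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}.{name}" if prefix else name)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        sub = f"{prefix}.{name}.{i}" if prefix else f"{name}.{i}"
                        yield from item.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        seen: set[int] = set()
        for mod_name, mod in self.named_modules(prefix):
            for name, val in vars(mod).items():
                if isinstance(val, Parameter) and id(val) not in seen:
                    seen.add(id(val))
                    yield (f"{mod_name}.{name}" if mod_name != "(root)" else name,
                           val)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        """Non-trainable state (batch-norm running statistics)."""
        for mod_name, mod in self.named_modules(prefix):
            for name in getattr(mod, "_buffers", ()):
                key = f"{mod_name}.{name}" if mod_name != "(root)" else name
                yield key, getattr(mod, name)

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer::{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, buf in self.named_buffers():
            buf[...] = state[f"buffer::{name}"]


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, dtype=np.float32):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(_init_rng().normal(
            0.0, std, size=(out_channels, in_channels // groups, k, k)).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups
        self.in_channels, self.out_channels, self.kernel_size = (
            in_channels, out_channels, k)

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.groups)


class ConvTranspose2d(Module):
    """Transposed convolution restricted to kernel == stride."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 2,
                 stride: int = 2, bias: bool = True, dtype=np.float32):
        super().__init__()
        if kernel_size != stride:
            raise ValueError("only kernel_size == stride is supported")
        fan_in = in_channels * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(_init_rng().normal(
            0.0, std, size=(in_channels, out_channels, kernel_size,
                            kernel_size)).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.stride = stride
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.weight = Parameter(np.ones(channels, dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training, self.momentum,
                              self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)
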