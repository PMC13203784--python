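"""Neural-network layers on top of :mod:`hybridseg.autodiff`.

Provides the module system (hierarchical parameter naming, train/eval
modes, state dicts) plus the layers the hybrid U-Net is built from:
convolutions, batch/layer normalisation, max pooling, transposed
convolution and dense projections. Parameter names follow the familiar
``block.sub.weight`` dotted convention; those names are the matching key
for warm-start weight transfer, so they are part of the public contract.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LayerNorm",
    "Linear",
    "Identity",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: containers register children by attribute assignment."""

    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, value in vars(self).items():
            if isinstance(value, Module):
                sub = f"{prefix}.{name}" if prefix else name
                yield from value.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            sub = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                yield sub, value
            elif isinstance(value, Module):
                yield from value.named_parameters(sub)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):
            sub = f"{prefix}.{name}" if prefix else name
            yield sub, getattr(self, name)
        for name, value in vars(self).items():
            if isinstance(value, Module):
                sub = f"{prefix}.{name}" if prefix else name
                yield from value.named_buffers(sub)

    # -- modes ----------------------------------------------------------
    def train(self) -> "Module":
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for _, m in self.named_modules():
            m.training = False
        return self

    # -- serialization ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(
        self, state: dict[str, np.ndarray], strict: bool = True
    ) -> dict[str, list[str]]:
        """Copy matching entries from ``state`` into this module.

        With ``strict=False`` only entries whose name AND shape match are
        loaded (warm-start semantics); the report lists the rest.
        """
        own_params = dict(self.named_parameters())
        own_buffers = {name: (None, name) for name, _ in self.named_buffers()}
        report = {"matched": [], "missing": [], "shape_mismatch": [], "unexpected": []}
        buffer_owners = {}
        for mod_name, mod in self.named_modules():
            for bname in getattr(mod, "_buffers", ()):
                full = f"{mod_name}.{bname}" if mod_name else bname
                buffer_owners[full] = (mod, bname)
        for name in list(own_params) + list(buffer_owners):
            if name not in state:
                report["missing"].append(name)
        for name, value in state.items():
            if name in own_params:
                target = own_params[name]
                if target.data.shape == value.shape:
                    target.data = value.astype(target.data.dtype).copy()
                    report["matched"].append(name)
                else:
                    report["shape_mismatch"].append(name)
            elif name in buffer_owners:
                mod, bname = buffer_owners[name]
                current = getattr(mod, bname)
                if current.shape == value.shape:
                    setattr(mod, bname, value.astype(current.dtype).copy())
                    report["matched"].append(name)
                else:
                    report["shape_mismatch"].append(name)
            else:
                report["unexpected"].append(name)
        if strict and (report["missing"] or report["shape_mismatch"] or report["unexpected"]):
            raise KeyError(f"strict load failed: {report}")
        return report

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        setattr(self, str(len(self._items)), module)
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i: int) -> Module:
        return self._items[i]


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


def _xavier(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if in_channels <= 0 or out_channels <= 0 or kernel_size <= 0:
            raise ValueError("convolution dimensions must be positive")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Kernel-2 stride-2 transposed convolution (the decoder upsampler)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(_kaiming(rng, (in_channels, out_channels, 2, 2), in_channels))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias)


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            n = x.data.size // x.shape[1]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            ).astype(np.float32)
            return x.batch_norm2d(self.weight, self.bias, mean, var, True, self.eps)
        return x.batch_norm2d(
            self.weight, self.bias, self.running_mean, self.running_var, False, self.eps
        )


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.weight, self.bias, self.eps)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_xavier(rng, (in_features, out_features), in_features, out_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
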