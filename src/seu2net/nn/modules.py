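"""Layer containers over the autodiff ops: modules, conv/BN units, state dicts."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Parameter, Tensor, batchnorm2d, conv2d, relu

__all__ = ["Module", "ModuleList", "Conv2d", "BatchNorm2d", "ConvBNReLU"]


class Module:
    """Minimal module container: child discovery, parameter/buffer walks,
    train/eval mode and flat state dicts keyed by dotted attribute paths."""

    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{path}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{path}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield path, value

    # -- modes -------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: buf for name, buf in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: p for name, p in self.named_parameters()}
        bufs = dict(self.named_buffers())
        for key, arr in state.items():
            if key in own:
                if own[key].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}: {own[key].data.shape} vs {arr.shape}")
                own[key].data = np.asarray(arr, dtype=own[key].data.dtype)
            elif key in bufs:
                bufs[key][...] = arr
            else:
                raise KeyError(f"unknown state entry {key!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    """An indexable list of child modules discovered by the walks above."""

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


class Conv2d(Module):
    """Same-padded stride-1 convolution; Kaiming-uniform initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        bound = float(np.sqrt(6.0 / fan_in))
        self.weight = Parameter(rng.uniform(-bound, bound, (out_ch, in_ch, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.weight = Parameter(np.ones(channels, dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(x, self.weight, self.bias, self.running_mean,
                           self.running_var, self.training, self.momentum, self.eps)


class ConvBNReLU(Module):
    """The elementary 3x3 conv -> batch norm -> rectifier unit.

    Padding equals the dilation, so spatial size is always preserved.
    """

    def __init__(self, in_ch: int, out_ch: int, dilation: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, dilation=dilation, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_ch, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))
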