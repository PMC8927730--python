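"""Parameterized layers with named state for checkpointing."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "Linear"]


class Module:
    """Base class: parameter discovery and flat name->array state dicts."""

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
        init: str = "he",
        init_std: float = 0.01,
    ):
        self.stride = stride
        self.padding = padding
        k = kernel_size
        shape = (out_channels, in_channels, k, k)
        if init == "zeros":
            w = np.zeros(shape, dtype=np.float32)
        elif init == "gaussian":
            w = (rng or np.random.default_rng()).normal(0, init_std, shape).astype(np.float32)
        else:
            w = _he_normal(rng or np.random.default_rng(), shape, in_channels * k * k)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Transposed convolution; defaults (kernel 4, stride 2, padding 1)
    double the spatial grid exactly."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 4,
        stride: int = 2,
        padding: int = 1,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
        init: str = "he",
    ):
        self.stride = stride
        self.padding = padding
        k = kernel_size
        shape = (in_channels, out_channels, k, k)
        if init == "zeros":
            w = np.zeros(shape, dtype=np.float32)
        else:
            w = _he_normal(rng or np.random.default_rng(), shape, in_channels * k * k)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor, output_size: Optional[tuple[int, int]] = None) -> Tensor:
        return F.conv_transpose2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding, output_size=output_size,
        )


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
        init: str = "he",
        init_std: float = 0.01,
    ):
        shape = (in_features, out_features)
        r = rng or np.random.default_rng()
        if init == "zeros":
            w = np.zeros(shape, dtype=np.float32)
        elif init == "gaussian":
            # mean-0 / small-std Gaussian, the classification-regression
            # layer initialization used in the training protocol
            w = r.normal(0, init_std, shape).astype(np.float32)
        else:
            w = _he_normal(r, shape, in_features)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out
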