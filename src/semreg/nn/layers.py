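"""Parameterised layers and a tiny module system for the registration nets."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, leaky_relu


class Module:
    """Base class: anything holding trainable :class:`Tensor` parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint tensor shape mismatch")
            p.data = a.astype(np.float32)


class Conv2d(Module):
    """3x3-style convolution with He initialisation (or zero init for heads)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        self.stride = stride
        self.padding = kernel // 2
        if zero_init:
            w = np.zeros((out_channels, in_channels, kernel, kernel))
        else:
            rng = rng if rng is not None else np.random.default_rng()
            fan_in = in_channels * kernel * kernel
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvAct(Module):
    """Convolution followed by a LeakyReLU(0.1) nonlinearity."""

    def __init__(self, cin: int, cout: int, stride: int = 1, rng=None):
        self.conv = Conv2d(cin, cout, stride=stride, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return leaky_relu(self.conv(x), 0.1)
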