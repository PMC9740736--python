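"""Parameterised building blocks (linear stacks) on the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["MLP", "Param"]


def Param(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    """He-style initialised weight tensor."""
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else 1
        scale = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class MLP:
    """Pointwise multi-layer perceptron: Linear→ReLU per hidden layer, final
    layer linear.  Applies to the last axis of its input."""

    def __init__(self, rng: np.random.Generator, widths: list[int],
                 final_relu: bool = False):
        self.widths = list(widths)
        self.final_relu = final_relu
        self.W = [Param(rng, widths[i], widths[i + 1])
                  for i in range(len(widths) - 1)]
        self.b = [Tensor(np.zeros(widths[i + 1]), requires_grad=True)
                  for i in range(len(widths) - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            x = x @ w + b
            if i < len(self.W) - 1 or self.final_relu:
                x = x.relu()
        return x

    def parameters(self) -> list[Tensor]:
        return self.W + self.b
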