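"""Dense layers and batch normalization built on the autodiff engine.

Initialization mirrors the conventional dense-layer default: weights and biases
drawn uniformly from ±1/sqrt(fan_in). Batch normalization keeps running
statistics (momentum 0.1) so that evaluation-mode output is independent of the
batch composition.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Parameter, Tensor

__all__ = ["Linear", "BatchNorm1d", "EncoderBlock", "ACTIVATIONS"]


ACTIVATIONS = {
    "sigmoid": lambda t: t.sigmoid(),
    "gelu": lambda t: t.gelu(),
}


class Linear:
    """Dense affine map ``x @ W + b`` with W of shape (fan_in, fan_out)."""

    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(fan_in)
        self.W = Parameter(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        self.b = Parameter(rng.uniform(-bound, bound, size=fan_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class BatchNorm1d:
    """Per-feature standardization with learned scale/shift.

    Training mode normalizes by the batch mean/variance (differentiated through);
    evaluation mode uses the tracked running statistics.
    """

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            y = xc * (var + self.eps) ** -0.5
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            y = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return y * self.gamma + self.beta

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class EncoderBlock:
    """linear -> activation -> (optional) batch normalization, in that order."""

    def __init__(
        self,
        fan_in: int,
        fan_out: int,
        activation: str,
        batch_norm: bool,
        rng: np.random.Generator,
    ):
        self.linear = Linear(fan_in, fan_out, rng)
        self.activation = activation
        self.bn = BatchNorm1d(fan_out) if batch_norm else None

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = ACTIVATIONS[self.activation](self.linear(x))
        if self.bn is not None:
            h = self.bn(h, training)
        return h

    def parameters(self) -> list[Parameter]:
        ps = self.linear.parameters()
        if self.bn is not None:
            ps += self.bn.parameters()
        return ps
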