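"""Dense network building blocks on top of the autodiff engine.

Initialization is He-style uniform fan-in scaling (appropriate for PReLU
activations) drawn from a caller-supplied numpy Generator, so that whole
models are reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Dense",
    "PReLU",
    "Sigmoid",
    "InstanceNorm",
    "BatchNorm",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for value in vars(self).values():
            for m in _collect_modules(value):
                m._set_mode(training)

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the module state (parameters + running stats)."""
        arrays = [p.data for p in self.parameters()]
        for value in vars(self).values():
            for m in _collect_modules(value):
                if isinstance(m, BatchNorm):
                    arrays.extend([m.running_mean, m.running_var])
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state does not match module structure")
        for dst, src in zip(arrays, state):
            dst[...] = src

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def _collect_modules(value):
    if isinstance(value, Module):
        yield value
        for sub in vars(value).values():
            yield from _collect_modules(sub)
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect_modules(v)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class PReLU(Module):
    """Parametric ReLU with one learnable slope per layer (init 0.25)."""

    def __init__(self, init: float = 0.25):
        super().__init__()
        self.slope = Parameter(np.array(init))

    def forward(self, x: Tensor) -> Tensor:
        return x.prelu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class InstanceNorm(Module):
    """Per-sample normalization across the feature axis (no affine terms).

    For tabular rows this standardizes each sample's embedding to zero mean
    and unit standard deviation over its elements, with epsilon inside the
    square root.
    """

    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5)


class BatchNorm(Module):
    """1-D batch normalization with running statistics for evaluation mode."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = x.var(axis=0, keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
        else:
            mu = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x
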