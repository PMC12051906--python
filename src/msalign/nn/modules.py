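"""Layer abstractions over the autograd engine.

Modules hold named :class:`Parameter` tensors and optional running buffers
(batch-norm statistics).  ``state_dict``/``load_state_dict`` expose a flat
name->array mapping used for checkpointing and bit-identical reproducibility
checks.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    avg_pool_time,
    conv_depthwise_spatial,
    conv_depthwise_temporal,
    conv_pointwise,
    conv_temporal,
)

__all__ = ["Parameter", "Module", "Linear", "BatchNorm", "Dropout"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container: tracks parameters, buffers, submodules, train mode."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: p.data for k, p in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            out.update(m.named_state(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")
        for k, v in own.items():
            np.copyto(v, state[k])

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        limit = np.sqrt(6.0 / (in_features + out_features))  # Glorot uniform
        self.weight = Parameter(rng.uniform(-limit, limit, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm(Module):
    """Normalize over all axes except ``channel_axis`` with running stats."""

    def __init__(self, num_features: int, channel_axis: int = 1,
                 momentum: float = 0.1, eps: float = 1e-3):
        super().__init__()
        self.axis = channel_axis
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self._buffers["running_mean"] = np.zeros(num_features, dtype=np.float32)
        self._buffers["running_var"] = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import batch_norm

        axes = tuple(i for i in range(x.ndim) if i != self.axis)
        bshape = tuple(-1 if i == self.axis else 1 for i in range(x.ndim))
        if self.training:
            out, mu, var = batch_norm(
                x, self.gamma.reshape(bshape), self.beta.reshape(bshape),
                axes, self.eps,
            )
            m = self.momentum
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm *= 1 - m
            rm += m * mu.reshape(-1)
            rv *= 1 - m
            rv += m * var.reshape(-1)
            return out
        mu = Tensor(self._buffers["running_mean"].reshape(bshape))
        var = Tensor(self._buffers["running_var"].reshape(bshape))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


class Dropout(Module):
    """Inverted dropout; the mask comes from an explicitly passed generator
    so training runs are reproducible from a single seed."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)
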