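"""Layer/module abstractions over the autodiff engine, plus AdamW.

Modules hold named :class:`~grainseg.tensor.Tensor` parameters and expose
``state_dict``/``load_state_dict`` for checkpointing (NumPy ``.npz`` files).
Initialisation draws from an explicit ``numpy.random.Generator`` so that a
whole model is a pure function of its config and seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter registration, train/eval mode, checkpoint I/O."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

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

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"checkpoint mismatch: missing={sorted(missing)[:5]} "
                f"extra={sorted(extra)[:5]}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as f:
            self.load_state_dict({k: f[k] for k in f.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated at +-2 std (resampled)."""
    x = rng.standard_normal(shape) * std
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.standard_normal(int(bad.sum())) * std
        bad = np.abs(x) > 2 * std
    return x


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = parameter(trunc_normal(rng, (in_dim, out_dim)))
        self.bias = parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x):
        return T.linear(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x):
        return T.layer_norm(x, self.gamma, self.beta, self.eps)


class Conv2d(Module):
    """3x3/1x1/4x4... convolution with He-uniform initialisation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        bound = float(np.sqrt(6.0 / fan_in))
        self.weight = parameter(
            rng.uniform(-bound, bound, (out_ch, in_ch, kernel, kernel))
        )
        self.bias = parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Mlp(Module):
    """Token-wise two-layer perceptron with GELU, used inside attention blocks."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x):
        return self.fc2(T.gelu(self.fc1(x)))


class DropPath(Module):
    """Stochastic depth: drop a residual branch per sample while training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"drop_path rate must be in [0, 1): {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        shape = (x.shape[0],) + (1,) * (x.ndim - 1)
        mask = (self.rng.random(shape) < keep).astype(np.float32) / keep
        return x * mask


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 5e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (
                (m / bc1) / (np.sqrt(v / bc2) + self.eps) + self.wd * p.data
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
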