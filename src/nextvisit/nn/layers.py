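"""Neural-network building blocks on top of the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, embedding

__all__ = ["Module", "Linear", "Embedding", "LayerNorm", "Dropout"]


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        _collect_named(self, "", out)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        current = {}
        _collect_named_params(self, "", current)
        missing = set(current) ^ set(state)
        if missing:
            raise ValueError(f"state dict key mismatch: {sorted(missing)}")
        for name, p in current.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data = np.asarray(state[name], dtype=np.float64).copy()


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_named(obj, prefix: str, out: dict[str, np.ndarray]) -> None:
    named: dict[str, Parameter] = {}
    _collect_named_params(obj, prefix, named)
    for k, p in named.items():
        out[k] = p.data.copy()


def _collect_named_params(obj, prefix: str, out: dict) -> None:
    if isinstance(obj, Parameter):
        out[prefix] = obj
        return
    if isinstance(obj, Module):
        for name, value in vars(obj).items():
            _collect_named_params(value, f"{prefix}.{name}" if prefix else name, out)
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _collect_named_params(v, f"{prefix}.{i}", out)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        scale = 1.0 / np.sqrt(in_dim)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_embeddings, dim)))
        self.n_embeddings = n_embeddings

    def __call__(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids)
        if ids.size and (ids.min() < 0 or ids.max() >= self.n_embeddings):
            raise ValueError(
                f"index out of range for embedding table of size {self.n_embeddings}"
            )
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity when ``training`` is false or p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self.training = False

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)
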