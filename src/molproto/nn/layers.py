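"""Parameterised building blocks (linear maps, MLPs, layer norm) on the
autodiff core, plus a tiny parameter registry used for checkpointing."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Parameter", "ParameterStore", "Linear", "MLP", "LayerNorm"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class ParameterStore:
    """Flat name -> Parameter mapping shared by a model's submodules."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}

    def add(self, name: str, data: np.ndarray) -> Parameter:
        if name in self._params:
            raise KeyError(f"duplicate parameter name: {name}")
        p = Parameter(data)
        self._params[name] = p
        return p

    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def items(self):
        return self._params.items()

    def values(self):
        return self._params.values()

    def names(self):
        return list(self._params)

    def zero_grad(self) -> None:
        for p in self._params.values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self._params.items():
            if k not in state:
                raise KeyError(f"missing parameter in state dict: {k}")
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{state[k].shape} vs {p.data.shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    """Affine map ``x @ W + b`` (bias optional)."""

    def __init__(self, store: ParameterStore, name: str, d_in: int, d_out: int,
                 rng: np.random.Generator, bias: bool = True):
        self.W = store.add(f"{name}.W", _glorot(rng, d_in, d_out))
        self.b = store.add(f"{name}.b", np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class MLP:
    """Two-layer perceptron with ReLU, the standard GIN update network."""

    def __init__(self, store: ParameterStore, name: str, d_in: int,
                 d_hidden: int, d_out: int, rng: np.random.Generator):
        self.fc1 = Linear(store, f"{name}.fc1", d_in, d_hidden, rng)
        self.fc2 = Linear(store, f"{name}.fc2", d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class LayerNorm:
    """Layer normalisation over the last axis with learnable gain/bias."""

    def __init__(self, store: ParameterStore, name: str, dim: int,
                 eps: float = 1e-5):
        self.g = store.add(f"{name}.g", np.ones(dim))
        self.b = store.add(f"{name}.b", np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred / (var + self.eps).sqrt() * self.g + self.b
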