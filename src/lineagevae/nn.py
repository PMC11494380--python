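"""Small neural-network building blocks on the numpy autodiff core.

Provides dense layers, layer normalization, a configurable MLP and an Adam
optimizer with the AMSGrad correction — everything the encoder, decoder and
dynamics networks need.  Weight initialization is Glorot-uniform from an
explicit ``numpy.random.Generator`` so that training runs are reproducible
bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

__all__ = ["Linear", "LayerNorm", "MLP", "Adam", "gaussian_log_density", "inverse_softplus"]


def inverse_softplus(y: float) -> float:
    """Return x with softplus(x) = y (y > 0)."""
    if y <= 0:
        raise ValueError("inverse_softplus requires a positive value")
    return float(y + np.log(-np.expm1(-y)))


class Module:
    """Base class: parameter collection and flat (name -> array) state."""

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

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                state[prefix + name] = value.data.copy()
            elif isinstance(value, Module):
                state.update(value.state_dict(prefix + name + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{prefix}{name}.{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                value.data = np.array(state[prefix + name], dtype=np.float64)
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{name}.{i}.")


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.weight = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Normalize the last axis to zero mean / unit variance, then affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gain + self.shift


class MLP(Module):
    """Feed-forward network: hidden layers with ReLU and optional layer norm."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int,
                 rng: np.random.Generator, layer_norm: bool = True):
        self.layers: list[Linear] = []
        self.norms: list[LayerNorm] = []
        d = n_in
        for h in hidden:
            self.layers.append(Linear(d, h, rng))
            self.norms.append(LayerNorm(h) if layer_norm else None)
            d = h
        self.head = Linear(d, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for lin, norm in zip(self.layers, self.norms):
            x = lin(x)
            if norm is not None:
                x = norm(x)
            x = x.relu()
        return self.head(x)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for lin in self.layers:
            params.extend(lin.parameters())
        for norm in self.norms:
            if norm is not None:
                params.extend(norm.parameters())
        params.extend(self.head.parameters())
        return params

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, lin in enumerate(self.layers):
            state.update(lin.state_dict(f"{prefix}layers.{i}."))
        for i, norm in enumerate(self.norms):
            if norm is not None:
                state.update(norm.state_dict(f"{prefix}norms.{i}."))
        state.update(self.head.state_dict(prefix + "head."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for i, lin in enumerate(self.layers):
            lin.load_state_dict(state, f"{prefix}layers.{i}.")
        for i, norm in enumerate(self.norms):
            if norm is not None:
                norm.load_state_dict(state, f"{prefix}norms.{i}.")
        self.head.load_state_dict(state, prefix + "head.")


class Adam:
    """Adam with the AMSGrad maximum-of-second-moments correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.vhat = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.vhat[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


_LOG_2PI = float(np.log(2.0 * np.pi))


def gaussian_log_density(x: Tensor, mean: Tensor, scale: Tensor) -> Tensor:
    """Diagonal-Gaussian log density, summed over the last axis.

    ``scale`` is the standard deviation (may broadcast, e.g. a scalar).
    """
    z = (x - mean) / scale
    per_dim = -0.5 * _LOG_2PI - scale.log() - 0.5 * z**2
    if isinstance(per_dim, Tensor) and per_dim.ndim > 0:
        return per_dim.sum(axis=-1)
    return per_dim
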