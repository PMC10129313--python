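"""Layers, parameter bookkeeping, and optimizers for the autodiff engine.

Parameters are :class:`~abframes.autodiff.Tensor` leaves with
``requires_grad=True``, collected recursively from ``Module`` attributes so
optimizers and checkpoints see a flat named dict.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, einsum, layer_norm

__all__ = ["Module", "Linear", "LayerNorm", "Sequential", "RAdam", "Adam",
           "cosine_lr"]


class Module:
    """Base class: recursive parameter discovery by attribute walk."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for k, v in val.parameters().items():
                    out[f"{name}.{k}"] = v
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for k, v in item.parameters().items():
                            out[f"{name}.{i}.{k}"] = v
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{name}.{i}"] = item
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)[:5]} "
                           f"extra={sorted(extra)[:5]}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


class Linear(Module):
    """Affine map on the last axis: y = x W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, scale: float | None = None):
        if scale is None:
            scale = 1.0 / math.sqrt(d_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        y = x.reshape(-1, self.d_in) @ self.W
        if self.b is not None:
            y = y + self.b
        return y.reshape(*lead, self.d_out)


class LayerNorm(Module):
    """Normalize over the last axis with learned gain/offset."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(d), requires_grad=True)
        self.o = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.g, self.o, self.eps)


class Sequential(Module):
    def __init__(self, layers: list):
        self.layers = layers

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class _StatefulOptimizer:
    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def _moments(self) -> Iterator[tuple[str, Tensor, np.ndarray, np.ndarray]]:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            yield k, p, self.m[k], self.v[k]


class Adam(_StatefulOptimizer):
    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, p, m, v in self._moments():
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RAdam(_StatefulOptimizer):
    """Rectified Adam: variance-rectified adaptive steps, SGD-with-momentum
    fallback while the adaptive variance estimate is untrustworthy."""

    def step(self) -> None:
        self.t += 1
        b2t = self.b2 ** self.t
        rho_inf = 2.0 / (1.0 - self.b2) - 1.0
        rho_t = rho_inf - 2.0 * self.t * b2t / (1.0 - b2t)
        bc1 = 1 - self.b1 ** self.t
        for k, p, m, v in self._moments():
            m_hat = m / bc1
            if rho_t > 4.0:
                v_hat = np.sqrt(v / (1.0 - b2t))
                r = math.sqrt(((rho_t - 4.0) * (rho_t - 2.0) * rho_inf)
                              / ((rho_inf - 4.0) * (rho_inf - 2.0) * rho_t))
                p.data = p.data - self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p.data = p.data - self.lr * m_hat


def cosine_lr(lr0: float, step: int, total_steps: int) -> float:
    """Cosine-annealed learning rate from lr0 to 0 over total_steps."""
    frac = min(max(step / max(total_steps, 1), 0.0), 1.0)
    return lr0 * 0.5 * (1.0 + math.cos(math.pi * frac))
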