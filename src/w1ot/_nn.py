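"""Minimal reverse-mode building blocks for small MLPs.

Everything here is plain NumPy with hand-derived backward passes.  The
networks in this package are narrow (widths <= 512), so explicit matmul
backprop is both fast enough on one CPU core and dependency-free.

Conventions
-----------
* Batches are row-major: ``X`` has shape ``(n, d)``.
* ``forward`` caches whatever ``backward`` needs; ``backward`` consumes the
  cache of the *most recent* forward and accumulates parameter gradients
  into ``.grads`` (call :meth:`Module.zero_grad` between optimizer steps).
* ``backward`` returns the gradient with respect to the layer input, so
  modules chain like autograd would.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Module",
    "Linear",
    "ReLU",
    "Sequential",
    "MLP",
    "Adam",
    "cosine_annealing",
    "softplus",
    "sigmoid",
]


def softplus(z: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + e^z)."""
    return np.logaddexp(0.0, z)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Module:
    """Base class: a list of named parameters plus matching gradients."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def parameters(self) -> list[np.ndarray]:
        return list(self.params.values())

    def gradients(self) -> list[np.ndarray]:
        return list(self.grads.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unknown parameter {k!r}")
            if self.params[k].shape != np.shape(v):
                raise ValueError(
                    f"shape mismatch for {k!r}: "
                    f"{self.params[k].shape} vs {np.shape(v)}"
                )
            self.params[k][...] = v

    def forward(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, G: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)


class Linear(Module):
    """Affine map ``X @ W.T + b`` with He-style initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        scale = np.sqrt(2.0 / in_dim)
        self.add_param("W", rng.normal(0.0, scale, size=(out_dim, in_dim)))
        self.add_param("b", np.zeros(out_dim))
        self._X: np.ndarray | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._X = X
        return X @ self.params["W"].T + self.params["b"]

    def backward(self, G: np.ndarray) -> np.ndarray:
        self.grads["W"] += G.T @ self._X
        self.grads["b"] += G.sum(axis=0)
        return G @ self.params["W"]


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._mask = X > 0
        return np.where(self._mask, X, 0.0)

    def backward(self, G: np.ndarray) -> np.ndarray:
        return G * self._mask


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        super().__init__()
        self.layers = layers

    def forward(self, X: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            X = layer.forward(X)
        return X

    def backward(self, G: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            G = layer.backward(G)
        return G

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.gradients()]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state_dict().items():
                out[f"{i}.{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, v in state.items():
            idx, name = key.split(".", 1)
            self.layers[int(idx)].load_state_dict({name: v})


class MLP(Sequential):
    """Plain ReLU multilayer perceptron mapping ``(n, in_dim) -> (n, out_dim)``."""

    def __init__(
        self,
        in_dim: int,
        hidden: list[int],
        out_dim: int,
        rng: np.random.Generator,
    ):
        layers: list[Module] = []
        prev = in_dim
        for width in hidden:
            layers.append(Linear(prev, width, rng))
            layers.append(ReLU())
            prev = width
        layers.append(Linear(prev, out_dim, rng))
        super().__init__(layers)
        self.in_dim, self.out_dim = in_dim, out_dim


class Adam:
    """Adam with optional decoupled weight decay.

    Works on any object exposing ``parameters()``/``gradients()`` returning
    aligned lists of arrays updated in place.
    """

    def __init__(
        self,
        module: Module,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.module = module
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p) for p in module.parameters()]
        self._v = [np.zeros_like(p) for p in module.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(
            self.module.parameters(), self.module.gradients(), self._m, self._v
        ):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p
            p -= self.lr * update


def cosine_annealing(
    step: int, total: int, lr_max: float, lr_min: float
) -> float:
    """Cosine-annealed learning rate at ``step`` of ``total`` (0-indexed)."""
    if total <= 1:
        return lr_min
    frac = min(step, total - 1) / (total - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + np.cos(np.pi * frac))
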