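"""1-Lipschitz networks: orthonormal linear layers + GroupSort activation.

A scalar-valued network built from gradient-norm-preserving pieces:

* linear layers whose weights are re-orthonormalized on every forward pass
  (Cayley transform by default, iterative Björck as the high-precision
  alternative), so the map never expands norms;
* the GroupSort activation, which sorts features within contiguous groups —
  its Jacobian is a permutation matrix, so every vector norm is preserved.

The composition is 1-Lipschitz by construction for *any* parameter values,
trained or not, and its input gradient has norm at most 1 everywhere.

Rectangular layers are handled by building a square orthogonal matrix of
size ``max(in_dim, out_dim)`` and slicing the leading rows/columns; the
slice of an orthogonal matrix is semi-orthogonal, hence non-expansive.
"""

from __future__ import annotations

import numpy as np

from ._nn import Module

__all__ = [
    "cayley_orthonormalize",
    "bjorck_orthonormalize",
    "groupsort",
    "OrthonormalLinearLayer",
    "GroupSortActivation",
    "LipschitzPotential",
    "potential_forward",
    "potential_gradient",
]


def cayley_orthonormalize(raw: np.ndarray) -> np.ndarray:
    """Map an unconstrained square matrix to an orthogonal matrix.

    Skew-symmetrizes ``raw`` into ``A = raw - raw.T`` and applies the Cayley
    transform ``W = (I - A) @ inv(I + A)``.  ``I + A`` is always invertible
    for real skew-symmetric ``A`` (its eigenvalues are ``1 + i*t``).

    The sign convention is fixed: ``raw = [[0, 1], [0, 0]]`` gives
    ``A = [[0, 1], [-1, 0]]`` and ``W = [[0, -1], [1, 0]]``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite entries in raw weight matrix")
    A = raw - raw.T
    eye = np.eye(raw.shape[0])
    # Solve (I + A)^T W^T = (I - A)^T rather than forming the inverse.
    return np.linalg.solve((eye + A).T, (eye - A).T).T


def bjorck_orthonormalize(
    raw: np.ndarray, iterations: int = 15, order: int = 1
) -> np.ndarray:
    """Iterate toward the closest orthonormal matrix (polar factor).

    First-order update ``W <- W @ (I + 0.5 * (I - W.T @ W))``, after
    pre-scaling the input by an upper bound on its spectral norm so the
    iteration is contractive.  Converges to the orthogonal polar factor of
    ``raw`` (for full-rank input).

    Parameters
    ----------
    iterations : number of update steps.
    order : Taylor order of the update; only ``1`` is implemented.
    """
    if order != 1:
        raise NotImplementedError("only the first-order Björck update is implemented")
    W = np.asarray(raw, dtype=float)
    if W.ndim != 2:
        raise ValueError(f"expected a matrix, got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError("non-finite entries in raw weight matrix")
    norm = np.linalg.norm(W, 2)
    if norm > 1.0:
        W = W / norm
    k = min(W.shape)
    eye = np.eye(k)
    prev = np.linalg.norm(W)
    for _ in range(iterations):
        if W.shape[0] >= W.shape[1]:
            W = W @ (eye + 0.5 * (eye - W.T @ W))
        else:
            W = (eye + 0.5 * (eye - W @ W.T)) @ W
        cur = np.linalg.norm(W)
        if not np.isfinite(cur) or cur > prev * 2.0 + 1.0:
            raise FloatingPointError(
                "Björck iteration diverged; pre-scale the input so its "
                "spectral norm is at most 1"
            )
        prev = cur
    return W


def groupsort(v: np.ndarray, group_size: int) -> np.ndarray:
    """Sort features ascending within contiguous groups of ``group_size``.

    Accepts a vector ``(width,)`` or a batch ``(n, width)``; the feature
    width must be divisible by ``group_size``.
    """
    v = np.asarray(v, dtype=float)
    width = v.shape[-1]
    if width % group_size != 0:
        raise ValueError(
            f"feature width {width} is not divisible by group size {group_size}"
        )
    shape = v.shape[:-1] + (width // group_size, group_size)
    return np.sort(v.reshape(shape), axis=-1).reshape(v.shape)


class OrthonormalLinearLayer(Module):
    """Linear layer whose effective weight is (semi-)orthonormal.

    The unconstrained parameter is a square ``s x s`` matrix with
    ``s = max(in_dim, out_dim)``; the effective weight is the leading
    ``out_dim x in_dim`` block of its orthonormalization, recomputed from the
    raw parameter on every forward pass (a parameterization, not a
    projection — optimizer steps act on ``raw``).  The bias is unconstrained:
    translations are 1-Lipschitz.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        method: str = "cayley",
        bjorck_iterations: int = 15,
    ):
        super().__init__()
        if method not in ("cayley", "bjorck"):
            raise ValueError(f"unknown orthonormalization method {method!r}")
        self.in_dim, self.out_dim = in_dim, out_dim
        self.method = method
        self.bjorck_iterations = bjorck_iterations
        s = max(in_dim, out_dim)
        self._s = s
        self.add_param("raw", rng.normal(0.0, 1.0 / np.sqrt(s), size=(s, s)))
        self.add_param("b", np.zeros(out_dim))
        # forward caches (consumed by backward)
        self._X: np.ndarray | None = None
        self._W_full: np.ndarray | None = None
        self._Q: np.ndarray | None = None
        self._bjorck_trace: list[np.ndarray] | None = None
        self._bjorck_scale: float = 1.0

    @property
    def weight(self) -> np.ndarray:
        """Effective ``out_dim x in_dim`` weight for the current raw parameter."""
        return self._orthonormal_full()[: self.out_dim, : self.in_dim]

    def _orthonormal_full(self) -> np.ndarray:
        raw = self.params["raw"]
        if self.method == "cayley":
            A = raw - raw.T
            eye = np.eye(self._s)
            self._Q = np.linalg.inv(eye + A)
            self._W_full = (eye - A) @ self._Q
        else:
            W = raw
            norm = np.linalg.norm(W, 2)
            self._bjorck_scale = max(norm, 1.0)
            W = W / self._bjorck_scale
            trace = [W]
            eye = np.eye(self._s)
            for _ in range(self.bjorck_iterations):
                W = W @ (eye + 0.5 * (eye - W.T @ W))
                trace.append(W)
            self._bjorck_trace = trace
            self._W_full = W
        return self._W_full

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._X = X
        W = self._orthonormal_full()[: self.out_dim, : self.in_dim]
        return X @ W.T + self.params["b"]

    def backward(self, G: np.ndarray, accumulate: bool = True) -> np.ndarray:
        W = self._W_full[: self.out_dim, : self.in_dim]
        if accumulate:
            G_W = np.zeros((self._s, self._s))
            G_W[: self.out_dim, : self.in_dim] = G.T @ self._X
            self.grads["raw"] += self._raw_grad(G_W)
            self.grads["b"] += G.sum(axis=0)
        return G @ W

    def _raw_grad(self, G_W: np.ndarray) -> np.ndarray:
        """Pull a gradient w.r.t. the full orthonormal matrix back to ``raw``."""
        if self.method == "cayley":
            # W = (I - A) Q with Q = (I + A)^-1  =>  dW = -(I + W) dA Q,
            # so dL/dA = -(I + W)^T G Q^T and A = raw - raw^T antisymmetrizes.
            eye = np.eye(self._s)
            G_A = -(eye + self._W_full).T @ G_W @ self._Q.T
            return G_A - G_A.T
        # Björck: unroll W_{k+1} = 1.5 W_k - 0.5 W_k W_k^T W_k.
        G = G_W
        for W in reversed(self._bjorck_trace[:-1]):
            G = 1.5 * G - 0.5 * (G @ W.T @ W + W @ G.T @ W + W @ W.T @ G)
        # pre-scaling treated as a constant (stop-gradient on the norm)
        return G / self._bjorck_scale


class GroupSortActivation(Module):
    """GroupSort: permutation-Jacobian activation, preserves every norm."""

    def __init__(self, group_size: int = 4):
        super().__init__()
        if group_size < 1:
            raise ValueError("group_size must be a positive integer")
        self.group_size = group_size
        self._order: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        g = self.group_size
        width = X.shape[-1]
        if width % g != 0:
            raise ValueError(
                f"feature width {width} is not divisible by group size {g}"
            )
        self._shape = X.shape
        blocks = X.reshape(X.shape[:-1] + (width // g, g))
        self._order = np.argsort(blocks, axis=-1, kind="stable")
        return np.take_along_axis(blocks, self._order, axis=-1).reshape(X.shape)

    def backward(self, G: np.ndarray) -> np.ndarray:
        g = self.group_size
        blocks = G.reshape(self._shape[:-1] + (self._shape[-1] // g, g))
        out = np.empty_like(blocks)
        np.put_along_axis(out, self._order, blocks, axis=-1)
        return out.reshape(self._shape)


class LipschitzPotential(Module):
    """Scalar 1-Lipschitz network: orthonormal layers + GroupSort.

    ``|f(x) - f(y)| <= ||x - y||`` holds for any parameter values, and the
    input gradient satisfies ``||grad f(x)|| <= 1`` everywhere.  At sort-tie
    points GroupSort is non-differentiable; the backward pass uses the
    stable-argsort subgradient (ties keep their original order).
    """

    def __init__(
        self,
        in_dim: int,
        hidden: tuple[int, ...] = (64, 64, 64, 64),
        group_size: int = 4,
        method: str = "cayley",
        seed: int | np.random.Generator = 0,
    ):
        super().__init__()
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        for width in hidden:
            if width % group_size != 0:
                raise ValueError(
                    f"hidden width {width} is not divisible by group size {group_size}"
                )
        self.in_dim = in_dim
        self.hidden = tuple(hidden)
        self.group_size = group_size
        self.method = method
        self.linears: list[OrthonormalLinearLayer] = []
        self.activations: list[GroupSortActivation] = []
        prev = in_dim
        for width in hidden:
            self.linears.append(
                OrthonormalLinearLayer(prev, width, rng, method=method)
            )
            self.activations.append(GroupSortActivation(group_size))
            prev = width
        self.linears.append(OrthonormalLinearLayer(prev, 1, rng, method=method))

    # -- Module plumbing over the child layers ------------------------------
    def zero_grad(self) -> None:
        for layer in self.linears:
            layer.zero_grad()

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.linears for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.linears for g in layer.gradients()]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.linears):
            for k, v in layer.state_dict().items():
                out[f"linear{i}.{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, v in state.items():
            name, pname = key.split(".", 1)
            self.linears[int(name.removeprefix("linear"))].load_state_dict(
                {pname: v}
            )

    # -- computation --------------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.in_dim:
            raise ValueError(
                f"expected input of shape (n, {self.in_dim}), got {X.shape}"
            )
        h = X
        for lin, act in zip(self.linears[:-1], self.activations):
            h = act.forward(lin.forward(h))
        return self.linears[-1].forward(h)[:, 0]

    def backward(self, G_out: np.ndarray, accumulate: bool = True) -> np.ndarray:
        """Backprop a gradient w.r.t. the scalar outputs; returns input grads."""
        G = np.asarray(G_out, dtype=float).reshape(-1, 1)
        G = self.linears[-1].backward(G, accumulate=accumulate)
        for lin, act in zip(
            reversed(self.linears[:-1]), reversed(self.activations)
        ):
            G = lin.backward(act.backward(G), accumulate=accumulate)
        return G

    def gradient(self, X: np.ndarray) -> np.ndarray:
        """Input gradient ``grad f(x_i)`` for every row of ``X``."""
        values = self.forward(np.asarray(X, dtype=float))
        return self.backward(np.ones_like(values), accumulate=False)


def potential_forward(net: LipschitzPotential, X: np.ndarray) -> np.ndarray:
    """Evaluate the potential on each row of ``X``; returns an ``(n,)`` vector."""
    return net.forward(X)


def potential_gradient(net: LipschitzPotential, X: np.ndarray) -> np.ndarray:
    """Row-wise input gradient of the potential, shape ``(n, d)``."""
    return net.gradient(X)
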