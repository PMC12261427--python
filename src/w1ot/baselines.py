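"""Reference predictors: identity, observed target, and balanced mean-shift.

The mean-shift model translates every source point by the displacement
between the (sample-balanced) source and target means — optionally in a
learned latent space, which reproduces the scGen-style baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import EmpiricalDistribution

__all__ = [
    "balance_samples",
    "MeanShiftModel",
    "mean_shift_fit",
    "mean_shift_predict",
    "identity_predict",
    "observed_baseline",
]


def balance_samples(
    A: np.ndarray, B: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the larger matrix (without replacement) to equal row counts."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    n, m = A.shape[0], B.shape[0]
    if n == m:
        return A, B
    rng = np.random.default_rng(seed)
    target = min(n, m)
    if n > m:
        A = A[rng.choice(n, size=target, replace=False)]
    else:
        B = B[rng.choice(m, size=target, replace=False)]
    return A, B


@dataclass
class MeanShiftModel:
    """Constant displacement ``delta = mean(target) - mean(source)``."""

    delta: np.ndarray
    space: str = "ambient"  # or "latent"


def mean_shift_fit(
    mu: EmpiricalDistribution | np.ndarray,
    nu: EmpiricalDistribution | np.ndarray,
    seed: int = 0,
    space: str = "ambient",
) -> MeanShiftModel:
    """Balance the samples, then record the displacement of the means."""
    X = mu.points if isinstance(mu, EmpiricalDistribution) else np.asarray(mu, float)
    Y = nu.points if isinstance(nu, EmpiricalDistribution) else np.asarray(nu, float)
    Xb, Yb = balance_samples(X, Y, seed=seed)
    return MeanShiftModel(delta=Yb.mean(axis=0) - Xb.mean(axis=0), space=space)


def mean_shift_predict(model: MeanShiftModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.delta.shape[0]:
        raise ValueError(
            f"expected {model.delta.shape[0]} features, got {X.shape[1]}"
        )
    return X + model.delta


def identity_predict(X: np.ndarray) -> np.ndarray:
    """The no-op baseline: prediction = input."""
    return np.asarray(X)


def observed_baseline(
    nu_train: EmpiricalDistribution | np.ndarray,
) -> np.ndarray:
    """The training target sample itself, used as the prediction."""
    if isinstance(nu_train, EmpiricalDistribution):
        return nu_train.points
    return np.asarray(nu_train, dtype=float)
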