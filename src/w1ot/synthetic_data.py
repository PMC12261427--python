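"""Seeded generators for 2D toy pairs and the overexpression simulator.

Every generator is a pure function of its parameters and seed, so the test
suite and benchmarks run without downloading anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.datasets import make_circles, make_moons, make_swiss_roll

from .solver import EmpiricalDistribution

__all__ = [
    "ToyPair",
    "make_bookshelf",
    "make_circles_pair",
    "make_swiss_roll_pair",
    "make_moons_pair",
    "make_gaussian_pair",
    "simulate_overexpression",
    "TOY_GENERATORS",
]


@dataclass
class ToyPair:
    """Source/target point clouds plus optional tracked marker indices."""

    source: EmpiricalDistribution
    target: EmpiricalDistribution
    markers: np.ndarray | None = None
    name: str = ""
    seed: int | None = None


def make_bookshelf(n: int = 1000, seed: int = 0) -> ToyPair:
    """Two narrow horizontal strips: source x in [0, 1], target x in [2, 3].

    y-values are Gaussian with standard deviation 0.001, so the pair is an
    almost-1D translation by 2.  Five marker points sit at the 10/30/50/70/90
    percent quantiles of the source x-values.
    """
    rng = np.random.default_rng(seed)
    src = np.column_stack([rng.uniform(0.0, 1.0, n), rng.normal(0.0, 0.001, n)])
    tgt = np.column_stack([rng.uniform(2.0, 3.0, n), rng.normal(0.0, 0.001, n)])
    quantiles = np.quantile(src[:, 0], [0.1, 0.3, 0.5, 0.7, 0.9])
    markers = np.array(
        [int(np.argmin(np.abs(src[:, 0] - q))) for q in quantiles]
    )
    return ToyPair(
        EmpiricalDistribution(src),
        EmpiricalDistribution(tgt),
        markers=markers,
        name="bookshelf",
        seed=seed,
    )


def make_circles_pair(
    n: int = 1000,
    noise: float = 0.05,
    seed: int = 0,
    target_scale: float = 4.0,
) -> ToyPair:
    """Four concentric rings: two source rings and two scaled target rings.

    Ring-membership labels (0 = outer, 1 = inner, following
    ``sklearn.datasets.make_circles``) are kept on both clouds so cross-ring
    transport can be measured.
    """
    src, src_lab = make_circles(
        n_samples=n, noise=noise, factor=0.5, random_state=seed
    )
    tgt, tgt_lab = make_circles(
        n_samples=n, noise=noise, factor=0.5, random_state=seed + 1
    )
    tgt = tgt * target_scale
    return ToyPair(
        EmpiricalDistribution(src, labels=src_lab),
        EmpiricalDistribution(tgt, labels=tgt_lab),
        name="circles",
        seed=seed,
    )


def make_swiss_roll_pair(
    n: int = 1000, seed: int = 0, noise: float = 0.0, scale: float = 0.1
) -> ToyPair:
    """Standard 2D Gaussian source; target = 2 of the 3 swiss-roll axes, scaled."""
    rng = np.random.default_rng(seed)
    src = rng.standard_normal((n, 2))
    roll, _ = make_swiss_roll(n_samples=n, noise=noise, random_state=seed)
    tgt = roll[:, [0, 2]] * scale
    return ToyPair(
        EmpiricalDistribution(src),
        EmpiricalDistribution(tgt),
        name="swiss_roll",
        seed=seed,
    )


def make_moons_pair(n: int = 1000, noise: float = 0.05, seed: int = 0) -> ToyPair:
    """Two interleaving half-circles; source = one moon, target = the other."""
    pts, lab = make_moons(n_samples=2 * n, noise=noise, random_state=seed)
    return ToyPair(
        EmpiricalDistribution(pts[lab == 0]),
        EmpiricalDistribution(pts[lab == 1]),
        name="moons",
        seed=seed,
    )


def make_gaussian_pair(
    shift,
    n: int = 1000,
    d: int | None = None,
    seed: int = 0,
) -> ToyPair:
    """Unit-covariance Gaussians related by a pure translation.

    The ideal W1 distance between the two laws is ``||shift||``, which makes
    this the closed-form fixture for dual-estimate and recovery checks.
    """
    shift = np.atleast_1d(np.asarray(shift, dtype=float))
    if d is None:
        d = shift.size
    if shift.size != d:
        raise ValueError("shift length must equal d")
    rng = np.random.default_rng(seed)
    src = rng.standard_normal((n, d))
    tgt = rng.standard_normal((n, d)) + shift
    return ToyPair(
        EmpiricalDistribution(src),
        EmpiricalDistribution(tgt),
        name="gaussian",
        seed=seed,
    )


def make_expression_matrix(
    n: int = 1200,
    d: int = 48,
    n_populations: int = 3,
    n_factors: int = 6,
    seed: int = 42,
) -> np.ndarray:
    """Surrogate imaging-feature/expression matrix with population structure.

    Cells are drawn from a mixture of ``n_populations`` latent Gaussian
    populations, mapped through shared factor loadings (correlated feature
    modules) and exponentiated to positive log-normal-like intensities.
    Per-feature detection dropout zeroes a fraction of entries; a handful of
    features are made poorly detected so expression-fraction filters have
    something to reject.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, 1.5, size=(n_populations, n_factors))
    comp = rng.integers(0, n_populations, size=n)
    z = centers[comp] + rng.normal(0.0, 0.5, size=(n, n_factors))
    loadings = rng.normal(0.0, 0.6, size=(n_factors, d))
    log_x = 0.4 * (z @ loadings) + rng.normal(0.0, 0.3, size=(n, d))
    X = np.exp(log_x)
    detect = rng.uniform(0.75, 1.0, size=d)
    detect[: max(1, d // 10)] = rng.uniform(0.1, 0.5, size=max(1, d // 10))
    X *= rng.uniform(size=(n, d)) < detect
    return X


TOY_GENERATORS = {
    "bookshelf": make_bookshelf,
    "circles": make_circles_pair,
    "swiss_roll": make_swiss_roll_pair,
    "moons": make_moons_pair,
}


def simulate_overexpression(
    X: np.ndarray,
    n_genes: int = 5,
    fold: float = 2.0,
    expr_frac: float = 0.6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fold-change upregulation of randomly chosen well-expressed features.

    Rows of ``X`` are split 50/50 into disjoint control and perturbed
    subsets; in the perturbed subset the chosen feature columns are
    multiplied by ``fold``.  Only features expressed (value > 0) in at least
    ``expr_frac`` of cells are eligible.

    Returns ``(source_subset, target_subset, perturbed_gene_indices)``.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    expressed = (X > 0).mean(axis=0)
    eligible = np.flatnonzero(expressed >= expr_frac)
    if eligible.size < n_genes:
        raise ValueError(
            f"only {eligible.size} features are expressed in at least "
            f"{expr_frac:.0%} of cells; {n_genes} required"
        )
    genes = np.sort(rng.choice(eligible, size=n_genes, replace=False))
    perm = rng.permutation(X.shape[0])
    half = X.shape[0] // 2
    source = X[perm[:half]].copy()
    target = X[perm[half:]].copy()
    target[:, genes] *= fold
    return source, target, genes
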