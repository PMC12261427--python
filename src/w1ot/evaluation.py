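"""Evaluation metrics: feature-mean agreement, multi-scale RBF MMD,
monotonicity diagnostics, rank-sum DE-gene selection and log-fold-change
error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

__all__ = [
    "MetricsReport",
    "DEFAULT_MMD_MULTIPLIERS",
    "mmd_rbf",
    "r2_means",
    "pearson_means",
    "l2_means",
    "monotonicity_violation_rate",
    "rank_de_genes",
    "logfc_mae",
    "compute_metrics",
]

# Kernel-width multipliers applied to the median-pairwise-distance heuristic.
DEFAULT_MMD_MULTIPLIERS = (2.0, 1.0, 0.5, 0.1, 0.01, 0.005)

_LOGFC_PSEUDOCOUNT = 1e-8


@dataclass
class MetricsReport:
    """One evaluation's metrics, JSON-serializable."""

    r2_means: float | None
    l2_means: float
    mmd: float
    mmd_scales: list[float]
    monotonicity_violation_rate: float | None = None
    logfc_mae: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        return cls(**json.loads(text))


def _as_2d(X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty input matrix")
    return X


def mmd_scales_from_data(
    X: np.ndarray, Y: np.ndarray, multipliers=DEFAULT_MMD_MULTIPLIERS
) -> np.ndarray:
    """RBF gammas: multipliers over the squared median pairwise distance."""
    pooled = np.vstack([X, Y])
    if pooled.shape[0] > 500:  # subsample the median heuristic for speed
        rng = np.random.default_rng(0)
        pooled = pooled[rng.choice(pooled.shape[0], 500, replace=False)]
    dists = cdist(pooled, pooled)
    med = np.median(dists[np.triu_indices_from(dists, k=1)])
    med2 = max(med * med, 1e-12)
    return np.asarray(multipliers, dtype=float) / med2


def mmd_rbf(
    X: np.ndarray, Y: np.ndarray, scales=None
) -> float:
    """Squared maximum mean discrepancy, biased (V-statistic) estimator.

    The RBF kernel is ``exp(-gamma * ||x - y||^2)``; ``scales`` is the list
    of gammas (default: :data:`DEFAULT_MMD_MULTIPLIERS` over the squared
    median pairwise distance).  The per-scale estimates are averaged.
    Symmetric in its arguments and zero for identical multisets.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("inputs must share dimensionality")
    # canonical argument order makes the estimator bitwise symmetric
    # (summation order would otherwise differ in the last ulp)
    if (Y.shape, Y.tobytes()) < (X.shape, X.tobytes()):
        X, Y = Y, X
    if scales is None:
        scales = mmd_scales_from_data(X, Y)
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    dxx = cdist(X, X, "sqeuclidean")
    dyy = cdist(Y, Y, "sqeuclidean")
    dxy = cdist(X, Y, "sqeuclidean")
    total = 0.0
    for gamma in scales:
        total += (
            np.exp(-gamma * dxx).mean()
            + np.exp(-gamma * dyy).mean()
            - 2.0 * np.exp(-gamma * dxy).mean()
        )
    return float(total / len(scales))


def pearson_means(X: np.ndarray, Y: np.ndarray) -> float | None:
    """Pearson correlation between the two feature-mean vectors."""
    mx = _as_2d(X).mean(axis=0)
    my = _as_2d(Y).mean(axis=0)
    if np.std(mx) == 0 or np.std(my) == 0:
        return None  # undefined on zero-variance mean vectors
    return float(np.corrcoef(mx, my)[0, 1])


def r2_means(X: np.ndarray, Y: np.ndarray) -> float | None:
    """Squared Pearson correlation of feature means (None if undefined)."""
    r = pearson_means(X, Y)
    return None if r is None else r * r


def l2_means(X: np.ndarray, Y: np.ndarray) -> float:
    """Euclidean distance between the feature-mean vectors."""
    mx = _as_2d(X).mean(axis=0)
    my = _as_2d(Y).mean(axis=0)
    if mx.shape != my.shape:
        raise ValueError("inputs must share dimensionality")
    return float(np.linalg.norm(mx - my))


def monotonicity_violation_rate(
    X: np.ndarray,
    TX: np.ndarray,
    pairs: np.ndarray | None = None,
    n_pairs: int = 10_000,
    seed: int = 0,
    tol: float = 1e-3,
) -> float:
    """Fraction of sampled point pairs whose relative order is inverted.

    For a pair (x1, x2), the map inverts their order exactly when the unit
    vectors of ``x1 - x2`` and ``T(x1) - T(x2)`` cancel; we count
    ``||u + v|| < tol`` as a violation.  Pairs coincident in either space
    are skipped.
    """
    X, TX = _as_2d(X), _as_2d(TX)
    if X.shape != TX.shape:
        raise ValueError("X and TX must have identical shapes")
    n = X.shape[0]
    if pairs is None:
        rng = np.random.default_rng(seed)
        pairs = rng.integers(0, n, size=(n_pairs, 2))
    pairs = np.asarray(pairs)
    dx = X[pairs[:, 0]] - X[pairs[:, 1]]
    dT = TX[pairs[:, 0]] - TX[pairs[:, 1]]
    nx = np.linalg.norm(dx, axis=1)
    nT = np.linalg.norm(dT, axis=1)
    valid = (nx > 1e-12) & (nT > 1e-12)
    if not valid.any():
        return 0.0
    u = dx[valid] / nx[valid, None]
    v = dT[valid] / nT[valid, None]
    return float((np.linalg.norm(u + v, axis=1) < tol).mean())


def rank_de_genes(
    control: np.ndarray, perturbed: np.ndarray, k: int = 50
) -> np.ndarray:
    """Top-k differential features by a two-sample Wilcoxon rank-sum score.

    Each feature gets a tie-corrected standardized rank-sum statistic (z);
    features are ranked by |z| with deterministic index tie-breaking.
    """
    control, perturbed = _as_2d(control), _as_2d(perturbed)
    if control.shape[1] != perturbed.shape[1]:
        raise ValueError("inputs must share dimensionality")
    d = control.shape[1]
    if k > d:
        raise ValueError(f"k={k} exceeds the number of features {d}")
    n1, n2 = control.shape[0], perturbed.shape[0]
    pooled = np.vstack([control, perturbed])
    ranks = np.apply_along_axis(rankdata, 0, pooled)
    R1 = ranks[:n1].sum(axis=0)
    N = n1 + n2
    expected = n1 * (N + 1) / 2.0
    # tie correction to the rank-sum variance, per feature
    var = np.empty(d)
    base = n1 * n2 * (N + 1) / 12.0
    for j in range(d):
        _, counts = np.unique(pooled[:, j], return_counts=True)
        tie_term = (counts**3 - counts).sum() / (N * (N - 1))
        var[j] = base - n1 * n2 * tie_term / 12.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (R1 - expected) / np.sqrt(var), 0.0)
    # stable sort on (-|z|, index): ties broken by feature index
    order = np.lexsort((np.arange(d), -np.abs(z)))
    return order[:k]


def _log2_means(M: np.ndarray) -> np.ndarray:
    return np.log2(_as_2d(M).mean(axis=0) + _LOGFC_PSEUDOCOUNT)


def logfc_mae(
    predicted: np.ndarray,
    observed: np.ndarray,
    gene_idx,
    control: np.ndarray | None = None,
) -> float:
    """Mean absolute error of per-gene log2 fold changes on ``gene_idx``.

    With ``control`` given, fold changes are relative to the control means;
    otherwise the log2 mean expressions are compared directly (the control
    term cancels in the difference either way).
    """
    gene_idx = np.atleast_1d(np.asarray(gene_idx, dtype=int))
    lp = _log2_means(predicted)[gene_idx]
    lo = _log2_means(observed)[gene_idx]
    if control is not None:
        lc = _log2_means(control)[gene_idx]
        lp, lo = lp - lc, lo - lc
    return float(np.abs(lp - lo).mean())


def compute_metrics(
    predicted: np.ndarray,
    observed: np.ndarray,
    source: np.ndarray | None = None,
    transported: np.ndarray | None = None,
    mmd_scales=None,
    metadata: dict | None = None,
) -> MetricsReport:
    """Bundle the standard metrics for one prediction into a report."""
    predicted, observed = _as_2d(predicted), _as_2d(observed)
    if mmd_scales is None:
        mmd_scales = mmd_scales_from_data(predicted, observed)
    mono = None
    if source is not None and transported is not None:
        mono = monotonicity_violation_rate(source, transported)
    return MetricsReport(
        r2_means=r2_means(predicted, observed),
        l2_means=l2_means(predicted, observed),
        mmd=mmd_rbf(predicted, observed, scales=mmd_scales),
        mmd_scales=list(np.atleast_1d(mmd_scales)),
        monotonicity_violation_rate=mono,
        metadata=metadata or {},
    )
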