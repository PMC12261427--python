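"""Two-stage Wasserstein-1 neural optimal transport solver.

Stage 1 maximizes the Kantorovich–Rubinstein dual over a 1-Lipschitz
GroupSort potential ``f``; at the optimum ``-loss`` estimates ``W1(mu, nu)``
and ``-grad f`` gives the transport direction.  Stage 2 freezes ``f`` and
adversarially trains a strictly positive step-size network ``eta`` so that

    T(x) = x - eta(x) * grad f(x)

pushes the source distribution onto the target.  The discriminator and the
step-size network play the original saturating GAN game.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, Adam, cosine_annealing, sigmoid, softplus
from .lipschitz_nets import LipschitzPotential

__all__ = [
    "EmpiricalDistribution",
    "PotentialTrainingConfig",
    "GanTrainingConfig",
    "StepSizeNetwork",
    "DiscriminatorNetwork",
    "TransportMap",
    "dual_loss",
    "train_potential",
    "transport_apply",
    "adversarial_losses",
    "train_step_size",
    "fit_w1ot",
]

_CLAMP_EPS = 1e-7


@dataclass
class EmpiricalDistribution:
    """A point cloud of samples, rows = cells, optionally labelled."""

    points: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1:
            raise ValueError("need at least one sample")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite entries in sample matrix")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.points.shape[0]:
                raise ValueError("labels length must match number of rows")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass
class PotentialTrainingConfig:
    iterations: int = 10_000
    batch_size: int = 256
    lr_max: float = 1e-2
    lr_min: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.5)
    hidden: tuple[int, ...] = (64, 64, 64, 64)
    group_size: int = 4
    method: str = "cayley"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if self.lr_max <= 0 or self.lr_min <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class GanTrainingConfig:
    iterations: int = 10_000
    batch_size: int = 256
    lr: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.9)
    hidden: tuple[int, ...] = (64, 64, 64, 64)
    # the exported step-size network uses an exponential moving average of
    # the generator weights; adversarial training oscillates and the final
    # iterate is unrepresentative.  0 disables averaging.
    ema_decay: float = 0.999
    # periodically score the averaged generator by training-set MMD and keep
    # the best checkpoint (the adversarial game can drift away from
    # alignment once the discriminator overfits).  0 disables selection.
    checkpoint_every: int = 250
    checkpoint_sample: int = 512

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


class StepSizeNetwork:
    """MLP mapping a sample to a strictly positive scalar via softplus."""

    def __init__(
        self,
        in_dim: int,
        hidden: tuple[int, ...] = (64, 64, 64, 64),
        rng: np.random.Generator | int = 0,
    ):
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.mlp = MLP(in_dim, list(hidden), 1, rng)
        self._z: np.ndarray | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._z = self.mlp.forward(np.asarray(X, dtype=float))
        return softplus(self._z)[:, 0]

    def backward(self, G_eta: np.ndarray) -> None:
        """Accumulate parameter grads given dL/d(eta) per sample."""
        self.mlp.backward(G_eta.reshape(-1, 1) * sigmoid(self._z))

    __call__ = forward


class DiscriminatorNetwork:
    """MLP classifier with sigmoid output clamped away from {0, 1}."""

    def __init__(
        self,
        in_dim: int,
        hidden: tuple[int, ...] = (64, 64, 64, 64),
        rng: np.random.Generator | int = 0,
    ):
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.mlp = MLP(in_dim, list(hidden), 1, rng)

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.mlp.forward(np.asarray(X, dtype=float))[:, 0]

    def prob(self, X: np.ndarray) -> np.ndarray:
        return np.clip(sigmoid(self.logits(X)), _CLAMP_EPS, 1.0 - _CLAMP_EPS)

    __call__ = prob


@dataclass
class TransportMap:
    """Frozen potential plus step-size network realizing the transport.

    With ``normalize_direction`` the displacement follows the unit gradient
    direction; otherwise the raw gradient is used (its norm is ~1 after
    training anyway).  Rows with a numerically zero gradient are returned
    unchanged when normalizing (warned about).
    """

    potential: LipschitzPotential
    step_size: StepSizeNetwork
    normalize_direction: bool = False

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return transport_apply(self, X)

    def displacement(self, X: np.ndarray) -> np.ndarray:
        return np.linalg.norm(X - self(X), axis=1)


def transport_apply(T: TransportMap, X: np.ndarray) -> np.ndarray:
    """Apply ``x -> x - eta(x) * direction(x)`` row-wise."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grad = T.potential.gradient(X)
    eta = T.step_size(X)
    if T.normalize_direction:
        norms = np.linalg.norm(grad, axis=1)
        degenerate = norms < 1e-12
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} rows have zero transport direction; "
                "returned unchanged",
                stacklevel=2,
            )
        safe = np.where(degenerate, 1.0, norms)
        direction = grad / safe[:, None]
        eta = np.where(degenerate, 0.0, eta)
    else:
        direction = grad
    return X - eta[:, None] * direction


def dual_loss(
    f: LipschitzPotential, batch_mu: np.ndarray, batch_nu: np.ndarray
) -> float:
    """Kantorovich–Rubinstein dual loss; ``-loss`` estimates W1 at optimum."""
    batch_mu = np.atleast_2d(batch_mu)
    batch_nu = np.atleast_2d(batch_nu)
    if batch_mu.shape[0] == 0 or batch_nu.shape[0] == 0:
        raise ValueError("batches must be non-empty")
    if batch_mu.shape[1] != batch_nu.shape[1]:
        raise ValueError("source and target batches must share dimensionality")
    return float(-f.forward(batch_mu).mean() + f.forward(batch_nu).mean())


def train_potential(
    mu: EmpiricalDistribution,
    nu: EmpiricalDistribution,
    cfg: PotentialTrainingConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[LipschitzPotential, np.ndarray]:
    """Stage 1: maximize the dual objective over the Lipschitz potential.

    Returns the trained potential and the per-iteration loss trace
    (minimized loss; the final W1 estimate is ``-trace[-1]``).
    """
    if cfg is None:
        cfg = PotentialTrainingConfig()
    if mu.dim != nu.dim:
        raise ValueError("source and target dimensionality differ")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    init_ss, batch_ss = ss.spawn(2)
    net = LipschitzPotential(
        mu.dim,
        hidden=cfg.hidden,
        group_size=cfg.group_size,
        method=cfg.method,
        seed=np.random.default_rng(init_ss),
    )
    rng = np.random.default_rng(batch_ss)
    opt = Adam(net, lr=cfg.lr_max, betas=cfg.betas)
    trace = np.empty(cfg.iterations)
    m = min(cfg.batch_size, mu.n)
    k = min(cfg.batch_size, nu.n)
    for it in range(cfg.iterations):
        bx = mu.points[rng.integers(0, mu.n, size=m)]
        by = nu.points[rng.integers(0, nu.n, size=k)]
        batch = np.vstack([bx, by])
        values = net.forward(batch)
        loss = -values[:m].mean() + values[m:].mean()
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite dual loss at iteration {it}; "
                "check input scaling and learning rate"
            )
        trace[it] = loss
        g = np.concatenate([np.full(m, -1.0 / m), np.full(k, 1.0 / k)])
        net.zero_grad()
        net.backward(g)
        opt.lr = cosine_annealing(it, cfg.iterations, cfg.lr_max, cfg.lr_min)
        opt.step()
    return net, trace


def adversarial_losses(
    D: DiscriminatorNetwork,
    T: TransportMap,
    batch_mu: np.ndarray,
    batch_nu: np.ndarray,
) -> tuple[float, float]:
    """Saturating GAN losses for the step-size generator and discriminator.

    gen_loss  = -E_mu[log D(T(x))]
    disc_loss = -E_nu[log D(y)] - E_mu[log(1 - D(T(x)))]
    with probabilities clamped to ``[eps, 1 - eps]``, ``eps = 1e-7``.
    """
    batch_mu = np.atleast_2d(batch_mu)
    batch_nu = np.atleast_2d(batch_nu)
    if batch_mu.shape[0] == 0 or batch_nu.shape[0] == 0:
        raise ValueError("batches must be non-empty")
    p_T = D.prob(T(batch_mu))
    p_y = D.prob(batch_nu)
    gen_loss = float(-np.log(p_T).mean())
    disc_loss = float(-np.log(p_y).mean() - np.log(1.0 - p_T).mean())
    return gen_loss, disc_loss


def train_step_size(
    f: LipschitzPotential,
    mu: EmpiricalDistribution,
    nu: EmpiricalDistribution,
    cfg: GanTrainingConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    normalize_direction: bool = False,
) -> tuple[StepSizeNetwork, DiscriminatorNetwork, dict]:
    """Stage 2: adversarially learn the step size with ``f`` frozen.

    Alternates one discriminator update with one generator (step-size)
    update per iteration.  The potential receives no parameter updates; a
    stuck-at-clamp generator loss is flagged in ``trace['warnings']``.
    """
    if cfg is None:
        cfg = GanTrainingConfig()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    eta_ss, disc_ss, batch_ss, eval_ss = ss.spawn(4)
    eta = StepSizeNetwork(mu.dim, cfg.hidden, np.random.default_rng(eta_ss))
    D = DiscriminatorNetwork(mu.dim, cfg.hidden, np.random.default_rng(disc_ss))
    rng = np.random.default_rng(batch_ss)
    opt_eta = Adam(eta.mlp, lr=cfg.lr, betas=cfg.betas)
    opt_D = Adam(D.mlp, lr=cfg.lr, betas=cfg.betas)

    m = min(cfg.batch_size, mu.n)
    k = min(cfg.batch_size, nu.n)
    gen_trace = np.empty(cfg.iterations)
    disc_trace = np.empty(cfg.iterations)
    clamp_ceiling = -np.log(_CLAMP_EPS) * 0.98
    stuck = 0
    mode_collapse = False
    ema = [p.copy() * 0.0 for p in eta.mlp.parameters()] if cfg.ema_decay else None

    select = cfg.checkpoint_every > 0
    if select:
        from .evaluation import mmd_rbf, mmd_scales_from_data

        eval_rng = np.random.default_rng(eval_ss)
        ns = cfg.checkpoint_sample
        eval_mu = (
            mu.points
            if mu.n <= ns
            else mu.points[eval_rng.choice(mu.n, ns, replace=False)]
        )
        eval_nu = (
            nu.points
            if nu.n <= ns
            else nu.points[eval_rng.choice(nu.n, ns, replace=False)]
        )
        eval_scales = mmd_scales_from_data(eval_mu, eval_nu)
        best_mmd = np.inf
        best_state = None
        mmd_checkpoints: list[tuple[int, float]] = []

    def _averaged_params():
        if ema is None:
            return [p.copy() for p in eta.mlp.parameters()]
        bias = 1.0 - cfg.ema_decay ** max(it + 1, 1)
        return [avg / bias for avg in ema]

    def _score_checkpoint():
        nonlocal best_mmd, best_state
        current = [p.copy() for p in eta.mlp.parameters()]
        for p, avg in zip(eta.mlp.parameters(), _averaged_params()):
            p[...] = avg
        Tx_eval = transport_apply(
            TransportMap(f, eta, normalize_direction), eval_mu
        )
        score = mmd_rbf(Tx_eval, eval_nu, scales=eval_scales)
        for p, c in zip(eta.mlp.parameters(), current):
            p[...] = c
        mmd_checkpoints.append((it + 1, float(score)))
        if score < best_mmd:
            best_mmd = score
            best_state = [p.copy() for p in _averaged_params()]

    for it in range(cfg.iterations):
        bx = mu.points[rng.integers(0, mu.n, size=m)]
        by = nu.points[rng.integers(0, nu.n, size=k)]
        grad_f = f.gradient(bx)  # frozen: no parameter accumulation
        if normalize_direction:
            norms = np.linalg.norm(grad_f, axis=1)
            direction = grad_f / np.where(norms < 1e-12, 1.0, norms)[:, None]
        else:
            direction = grad_f

        # --- discriminator step: -E[log D(y)] - E[log(1 - D(T(x)))] -------
        step = eta.forward(bx)
        Tx = bx - step[:, None] * direction
        D.mlp.zero_grad()
        z_y = D.mlp.forward(by)
        disc_loss = softplus(-z_y).mean()
        D.mlp.backward(-sigmoid(-z_y) / k)
        z_T = D.mlp.forward(Tx)
        disc_loss += softplus(z_T).mean()
        D.mlp.backward(sigmoid(z_T) / m)
        opt_D.step()

        # --- generator step: -E[log D(T(x))] -------------------------------
        step = eta.forward(bx)
        Tx = bx - step[:, None] * direction
        z_T = D.mlp.forward(Tx)
        gen_loss = softplus(-z_T).mean()
        dTx = D.mlp.backward(-sigmoid(-z_T) / m)
        D.mlp.zero_grad()  # discard discriminator accumulation from this pass
        eta.mlp.zero_grad()
        eta.backward(-(dTx * direction).sum(axis=1))
        opt_eta.step()
        if ema is not None:
            d = cfg.ema_decay
            for avg, p in zip(ema, eta.mlp.parameters()):
                avg *= d
                avg += (1.0 - d) * p
        if select and ((it + 1) % cfg.checkpoint_every == 0 or it == cfg.iterations - 1):
            _score_checkpoint()

        if not (np.isfinite(gen_loss) and np.isfinite(disc_loss)):
            raise RuntimeError(f"non-finite GAN loss at iteration {it}")
        gen_trace[it] = gen_loss
        disc_trace[it] = disc_loss
        stuck = stuck + 1 if gen_loss > clamp_ceiling else 0
        if stuck >= 200 and not mode_collapse:
            mode_collapse = True
            warnings.warn(
                "generator loss pinned at the clamp for 200 iterations; "
                "possible mode collapse",
                stacklevel=2,
            )

    it = cfg.iterations - 1
    if select and best_state is not None:
        for p, bp in zip(eta.mlp.parameters(), best_state):
            p[...] = bp
    else:
        for p, avg in zip(eta.mlp.parameters(), _averaged_params()):
            p[...] = avg

    trace = {
        "gen_loss": gen_trace,
        "disc_loss": disc_trace,
        "warnings": ["mode_collapse"] if mode_collapse else [],
    }
    if select:
        trace["mmd_checkpoints"] = mmd_checkpoints
        trace["best_checkpoint_mmd"] = float(best_mmd)
    return eta, D, trace


def fit_w1ot(
    mu: EmpiricalDistribution,
    nu: EmpiricalDistribution,
    potential_cfg: PotentialTrainingConfig | None = None,
    gan_cfg: GanTrainingConfig | None = None,
    seed: int = 0,
    normalize_direction: bool = False,
) -> tuple[TransportMap, dict]:
    """Run both stages and return the composed transport map plus traces."""
    if mu.dim != nu.dim:
        raise ValueError("source and target dimensionality differ")
    ss = np.random.SeedSequence(seed)
    pot_ss, gan_ss = ss.spawn(2)
    f, pot_trace = train_potential(mu, nu, potential_cfg, seed=pot_ss)
    frozen = {k: v.copy() for k, v in f.state_dict().items()}
    eta, D, gan_trace = train_step_size(
        f, mu, nu, gan_cfg, seed=gan_ss, normalize_direction=normalize_direction
    )
    for k, v in f.state_dict().items():
        if not np.array_equal(frozen[k], v):  # stage separation guarantee
            raise AssertionError("potential parameters changed during stage 2")
    traces = {
        "potential_loss": pot_trace,
        "w1_estimate": float(-pot_trace[-1]),
        "gan": gan_trace,
    }
    return TransportMap(f, eta, normalize_direction), traces
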