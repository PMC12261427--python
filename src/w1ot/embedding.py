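"""Autoencoder defining the latent space used for high-dimensional data.

A plain ReLU encoder/decoder pair trained on mean squared reconstruction
error with Adam (weight decay 1e-5), keeping the checkpoint with the best
validation loss.  Transport then runs on ``encode(X)`` and predictions are
decoded back to feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, Adam

__all__ = ["AutoencoderConfig", "Autoencoder", "train_autoencoder", "encode", "decode"]


@dataclass
class AutoencoderConfig:
    hidden: tuple[int, ...] = (512, 512)
    latent_dim: int = 50
    iterations: int = 20_000  # full-scale runs use 250_000
    batch_size: int = 256
    lr: float = 1e-3
    weight_decay: float = 1e-5
    val_fraction: float = 0.1
    val_every: int = 250

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


class Autoencoder:
    """Encoder/decoder MLP pair with mirrored hidden widths."""

    def __init__(
        self,
        in_dim: int,
        cfg: AutoencoderConfig,
        rng: np.random.Generator | int = 0,
    ):
        if cfg.latent_dim >= in_dim:
            raise ValueError("latent dim must be smaller than the input dim")
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.in_dim = in_dim
        self.cfg = cfg
        self.encoder = MLP(in_dim, list(cfg.hidden), cfg.latent_dim, rng)
        self.decoder = MLP(cfg.latent_dim, list(cfg.hidden)[::-1], in_dim, rng)
        self.best_val_loss: float = np.inf
        self.train_mse: float | None = None

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.in_dim:
            raise ValueError(f"expected {self.in_dim} features, got {X.shape[1]}")
        return self.encoder.forward(X)

    def decode(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.cfg.latent_dim:
            raise ValueError(
                f"expected {self.cfg.latent_dim} latent features, got {Z.shape[1]}"
            )
        return self.decoder.forward(Z)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"enc.{k}": v for k, v in self.encoder.state_dict().items()}
        out.update({f"dec.{k}": v for k, v in self.decoder.state_dict().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, v in state.items():
            part, rest = key.split(".", 1)
            (self.encoder if part == "enc" else self.decoder).load_state_dict(
                {rest: v}
            )


def train_autoencoder(
    X: np.ndarray,
    cfg: AutoencoderConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[Autoencoder, dict]:
    """Train on a random holdout split; return the best-validation model.

    The trace dict records the training-loss curve, the validation curve
    (evaluated every ``cfg.val_every`` iterations) and the best validation
    loss.  Aborts on a non-finite loss.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples to train the autoencoder")
    if cfg is None:
        cfg = AutoencoderConfig()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    init_ss, split_ss, batch_ss = ss.spawn(3)

    split_rng = np.random.default_rng(split_ss)
    perm = split_rng.permutation(X.shape[0])
    n_val = max(1, int(round(cfg.val_fraction * X.shape[0])))
    X_val, X_train = X[perm[:n_val]], X[perm[n_val:]]

    model = Autoencoder(X.shape[1], cfg, np.random.default_rng(init_ss))
    rng = np.random.default_rng(batch_ss)
    params = _JointParams(model)
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    n = X_train.shape[0]
    bs = min(cfg.batch_size, n)
    train_curve = np.empty(cfg.iterations)
    val_curve: list[tuple[int, float]] = []
    best_state = model.state_dict()

    for it in range(cfg.iterations):
        batch = X_train[rng.integers(0, n, size=bs)]
        Z = model.encoder.forward(batch)
        Xhat = model.decoder.forward(Z)
        diff = Xhat - batch
        loss = float((diff**2).mean())
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite reconstruction loss at iteration {it}")
        train_curve[it] = loss
        G = 2.0 * diff / diff.size
        model.encoder.zero_grad()
        model.decoder.zero_grad()
        model.encoder.backward(model.decoder.backward(G))
        opt.step()

        if it % cfg.val_every == 0 or it == cfg.iterations - 1:
            val_loss = float(((model.reconstruct(X_val) - X_val) ** 2).mean())
            val_curve.append((it, val_loss))
            if val_loss < model.best_val_loss:
                model.best_val_loss = val_loss
                best_state = model.state_dict()

    model.load_state_dict(best_state)
    model.train_mse = float(((model.reconstruct(X) - X) ** 2).mean())
    trace = {
        "train_loss": train_curve,
        "val_loss": val_curve,
        "best_val_loss": model.best_val_loss,
    }
    return model, trace


class _JointParams:
    """Adapter exposing encoder+decoder parameters as one module to Adam."""

    def __init__(self, model: Autoencoder):
        self.model = model

    def parameters(self) -> list[np.ndarray]:
        return self.model.encoder.parameters() + self.model.decoder.parameters()

    def gradients(self) -> list[np.ndarray]:
        return self.model.encoder.gradients() + self.model.decoder.gradients()


def encode(model: Autoencoder, X: np.ndarray) -> np.ndarray:
    return model.encode(X)


def decode(model: Autoencoder, Z: np.ndarray) -> np.ndarray:
    return model.decode(Z)
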