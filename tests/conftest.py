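"""Shared fixtures.

Training runs are expensive, so fitted models are session-scoped and reused
by both the unit tests and the acceptance suite.  Iteration counts are
desk-scale reductions of the full defaults; seeds are fixed throughout.
"""

from __future__ import annotations

import numpy as np
import pytest

from w1ot.solver import (
    EmpiricalDistribution,
    GanTrainingConfig,
    PotentialTrainingConfig,
    TransportMap,
    train_potential,
    train_step_size,
)
from w1ot.synthetic_data import make_gaussian_pair


@pytest.fixture(scope="session")
def gaussian_pair():
    """2D unit Gaussians with means (0,0) and (4,0), 2000 points each."""
    return make_gaussian_pair([4.0, 0.0], n=2000, seed=11)


@pytest.fixture(scope="session")
def gaussian_potential(gaussian_pair):
    """Stage 1 trained at the documented scale: 2000 iterations, batch 256."""
    cfg = PotentialTrainingConfig(iterations=2000)
    f, trace = train_potential(
        gaussian_pair.source, gaussian_pair.target, cfg, seed=1
    )
    return f, trace


@pytest.fixture(scope="session")
def gaussian_transport(gaussian_pair, gaussian_potential):
    """Both stages on the translated-Gaussian pair."""
    f, pot_trace = gaussian_potential
    frozen = {k: v.copy() for k, v in f.state_dict().items()}
    eta, D, gan_trace = train_step_size(
        f,
        gaussian_pair.source,
        gaussian_pair.target,
        GanTrainingConfig(iterations=4000),
        seed=2,
    )
    return {
        "pair": gaussian_pair,
        "potential": f,
        "potential_frozen_state": frozen,
        "potential_trace": pot_trace,
        "eta": eta,
        "discriminator": D,
        "gan_trace": gan_trace,
        "transport": TransportMap(f, eta),
    }


def _fit_toy(pair, pot_iterations=1500, gan_iterations=1500, seed=0):
    from w1ot.solver import fit_w1ot

    transport, traces = fit_w1ot(
        pair.source,
        pair.target,
        PotentialTrainingConfig(iterations=pot_iterations),
        GanTrainingConfig(iterations=gan_iterations),
        seed=seed,
    )
    return pair, transport, traces


@pytest.fixture(scope="session")
def bookshelf_fit():
    from w1ot.synthetic_data import make_bookshelf

    return _fit_toy(make_bookshelf(n=600, seed=3), seed=3)


@pytest.fixture(scope="session")
def circles_fit():
    from w1ot.synthetic_data import make_circles_pair

    return _fit_toy(make_circles_pair(n=600, noise=0.03, seed=4), seed=4)


@pytest.fixture(scope="session")
def moons_fit():
    from w1ot.synthetic_data import make_moons_pair

    return _fit_toy(
        make_moons_pair(n=1000, noise=0.05, seed=5),
        pot_iterations=2000,
        gan_iterations=4000,
        seed=5,
    )


@pytest.fixture(scope="session")
def swiss_roll_fit():
    from w1ot.synthetic_data import make_swiss_roll_pair

    return _fit_toy(
        make_swiss_roll_pair(n=1000, seed=6),
        pot_iterations=2000,
        gan_iterations=4000,
        seed=6,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def expression_matrix():
    """Structured positive expression data: 1200 cells x 48 features."""
    from w1ot.synthetic_data import make_expression_matrix

    return make_expression_matrix(seed=42)


@pytest.fixture(scope="session")
def overexpression_result(expression_matrix):
    """Scaled-down overexpression sensitivity experiment.

    Simulates a 2-fold/5-gene upregulation, splits 80/20, then trains the
    ambient-space transport and the latent mean-shift baseline (autoencoder
    + balanced displacement, the scGen-style predictor) and scores both by
    log-fold-change mean absolute error on the held-out split.
    """
    from w1ot.baselines import balance_samples, mean_shift_fit, mean_shift_predict
    from w1ot.embedding import AutoencoderConfig, train_autoencoder
    from w1ot.evaluation import logfc_mae
    from w1ot.io import iid_split
    from w1ot.solver import fit_w1ot
    from w1ot.synthetic_data import simulate_overexpression

    src, tgt, genes = simulate_overexpression(expression_matrix, seed=0)
    tr_s, te_s = iid_split(src.shape[0], 0.8, seed=1)
    tr_t, te_t = iid_split(tgt.shape[0], 0.8, seed=2)
    Xtr, Xte = src[tr_s], src[te_s]
    Ytr, Yte = tgt[tr_t], tgt[te_t]

    transport, _ = fit_w1ot(
        EmpiricalDistribution(Xtr),
        EmpiricalDistribution(Ytr),
        PotentialTrainingConfig(iterations=2000),
        GanTrainingConfig(iterations=4000),
        seed=3,
    )
    w1ot_mae = logfc_mae(transport(Xte), Yte, genes, control=Xte)

    ae, _ = train_autoencoder(
        np.vstack([Xtr, Ytr]),
        AutoencoderConfig(hidden=(32, 32), latent_dim=8, iterations=8000),
        seed=4,
    )
    Za, Zb = balance_samples(ae.encode(Xtr), ae.encode(Ytr), seed=5)
    model = mean_shift_fit(Za, Zb, seed=5, space="latent")
    pred = ae.decode(mean_shift_predict(model, ae.encode(Xte)))
    latent_mae = logfc_mae(pred, Yte, genes, control=Xte)

    return {
        "genes": genes,
        "w1ot_mae": w1ot_mae,
        "latent_mean_shift_mae": latent_mae,
        "identity_mae": logfc_mae(Xte, Yte, genes, control=Xte),
    }
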