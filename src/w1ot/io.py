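"""Checkpoint and data I/O.

Checkpoints are directories of JSON files — a ``manifest.json`` describing
architectures, configs, seeds and loss traces, plus one ``*.json`` of
nested-list parameter arrays per network — so they stay plain-text and
diffable.  Matrices travel as headered CSV (rows = cells) or as h5ad with a
condition column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import Autoencoder, AutoencoderConfig
from .lipschitz_nets import LipschitzPotential
from .solver import (
    DiscriminatorNetwork,
    EmpiricalDistribution,
    StepSizeNetwork,
    TransportMap,
)

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "read_matrix_csv",
    "write_matrix_csv",
    "load_condition_pair",
    "iid_split",
    "ood_split",
]

_FORMAT_VERSION = 1


def _state_to_json(state: dict[str, np.ndarray]) -> dict:
    return {k: v.tolist() for k, v in state.items()}


def _state_from_json(state: dict) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in state.items()}


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_checkpoint(
    outdir: str | Path,
    transport: TransportMap,
    discriminator: DiscriminatorNetwork | None = None,
    autoencoder: Autoencoder | None = None,
    config: dict | None = None,
    traces: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write a transport-map checkpoint directory; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    f = transport.potential
    manifest = {
        "format_version": _FORMAT_VERSION,
        "seed": seed,
        "config": _jsonable(config or {}),
        "traces": _jsonable(traces or {}),
        "potential": {
            "in_dim": f.in_dim,
            "hidden": list(f.hidden),
            "group_size": f.group_size,
            "method": f.method,
        },
        "step_size": {
            "in_dim": transport.step_size.mlp.in_dim,
            "hidden": [
                layer.out_dim
                for layer in transport.step_size.mlp.layers[:-1]
                if hasattr(layer, "out_dim")
            ],
        },
        "normalize_direction": transport.normalize_direction,
        "has_discriminator": discriminator is not None,
        "autoencoder": None,
    }
    (outdir / "potential.json").write_text(
        json.dumps(_state_to_json(f.state_dict()))
    )
    (outdir / "step_size.json").write_text(
        json.dumps(_state_to_json(transport.step_size.mlp.state_dict()))
    )
    if discriminator is not None:
        (outdir / "discriminator.json").write_text(
            json.dumps(_state_to_json(discriminator.mlp.state_dict()))
        )
    if autoencoder is not None:
        manifest["autoencoder"] = {
            "in_dim": autoencoder.in_dim,
            "hidden": list(autoencoder.cfg.hidden),
            "latent_dim": autoencoder.cfg.latent_dim,
        }
        (outdir / "autoencoder.json").write_text(
            json.dumps(_state_to_json(autoencoder.state_dict()))
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def load_checkpoint(
    ckpt_dir: str | Path,
) -> tuple[TransportMap, Autoencoder | None, dict]:
    """Rebuild the transport map (and autoencoder, if any) from a checkpoint."""
    ckpt_dir = Path(ckpt_dir)
    manifest = json.loads((ckpt_dir / "manifest.json").read_text())
    p = manifest["potential"]
    potential = LipschitzPotential(
        p["in_dim"],
        hidden=tuple(p["hidden"]),
        group_size=p["group_size"],
        method=p["method"],
        seed=0,
    )
    potential.load_state_dict(
        _state_from_json(json.loads((ckpt_dir / "potential.json").read_text()))
    )
    s = manifest["step_size"]
    step = StepSizeNetwork(s["in_dim"], tuple(s["hidden"]), 0)
    step.mlp.load_state_dict(
        _state_from_json(json.loads((ckpt_dir / "step_size.json").read_text()))
    )
    transport = TransportMap(
        potential, step, normalize_direction=manifest["normalize_direction"]
    )
    autoencoder = None
    if manifest.get("autoencoder"):
        a = manifest["autoencoder"]
        autoencoder = Autoencoder(
            a["in_dim"],
            AutoencoderConfig(hidden=tuple(a["hidden"]), latent_dim=a["latent_dim"]),
            0,
        )
        autoencoder.load_state_dict(
            _state_from_json(
                json.loads((ckpt_dir / "autoencoder.json").read_text())
            )
        )
    return transport, autoencoder, manifest


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a headered CSV of cells x features; returns (matrix, feature names)."""
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), list(df.columns)


def write_matrix_csv(
    path: str | Path, X: np.ndarray, features: list[str] | None = None
) -> None:
    X = np.atleast_2d(np.asarray(X))
    if features is None:
        features = [f"feature_{j}" for j in range(X.shape[1])]
    pd.DataFrame(X, columns=features).to_csv(path, index=False)


def load_condition_pair(
    path: str | Path,
    condition_col: str,
    control_label: str,
    perturbed_label: str,
    label_col: str | None = None,
):
    """Split an h5ad container into (control, perturbed) point clouds.

    ``label_col`` optionally attaches per-cell labels (e.g. cell type) used
    for out-of-distribution splits.
    """
    import anndata as ad

    adata = ad.read_h5ad(path)
    if condition_col not in adata.obs.columns:
        raise KeyError(
            f"condition column {condition_col!r} not found in obs "
            f"(available: {list(adata.obs.columns)})"
        )
    conditions = adata.obs[condition_col].astype(str)
    for label in (control_label, perturbed_label):
        if not (conditions == label).any():
            raise ValueError(
                f"label {label!r} absent from column {condition_col!r}"
            )
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    labels = None
    if label_col is not None:
        if label_col not in adata.obs.columns:
            raise KeyError(f"label column {label_col!r} not found in obs")
        labels = adata.obs[label_col].astype(str).to_numpy()

    def subset(mask):
        return EmpiricalDistribution(
            X[mask], labels=labels[mask] if labels is not None else None
        )

    mu = subset((conditions == control_label).to_numpy())
    nu = subset((conditions == perturbed_label).to_numpy())
    return mu, nu, list(adata.var_names)


def iid_split(
    n: int, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test index split."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cut = int(round(train_fraction * n))
    return np.sort(perm[:cut]), np.sort(perm[cut:])


def ood_split(
    labels: np.ndarray, heldout_label: str
) -> tuple[np.ndarray, np.ndarray]:
    """Train on all labels except ``heldout_label``; test only on it."""
    labels = np.asarray(labels).astype(str)
    mask = labels == str(heldout_label)
    if not mask.any():
        raise ValueError(f"label {heldout_label!r} absent from data")
    return np.flatnonzero(~mask), np.flatnonzero(mask)
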