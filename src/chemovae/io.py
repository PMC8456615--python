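"""Checkpoint and embedding serialization.

VAE/AE weights go to an ``.npz`` archive with a JSON architecture sidecar
(same stem, ``.json``), so a checkpoint is self-describing. Linear
embeddings (PCA/ICA) are written as TSV loadings plus JSON metadata.
Min-max scaling parameters are written as a three-column TSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import LinearEmbedding
from .preprocess import MinMaxParams
from .vae import VAEArchitecture, VAEParams


def save_vae(params: VAEParams, path: str) -> None:
    """Write weights to ``path`` (.npz) and the architecture to a .json
    sidecar with the same stem."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, (W, b) in enumerate(params.trunk):
        arrays[f"trunk_{i}_W"], arrays[f"trunk_{i}_b"] = W, b
    arrays["mu_W"], arrays["mu_b"] = params.mu_head
    if params.logvar_head is not None:
        arrays["logvar_W"], arrays["logvar_b"] = params.logvar_head
    for i, (W, b) in enumerate(params.decoder):
        arrays[f"dec_{i}_W"], arrays[f"dec_{i}_b"] = W, b
    np.savez(path, **arrays)
    sidecar = {
        "arch": asdict(params.arch),
        "n_features": params.n_features,
        "trained": params.trained,
        "variational": params.variational,
        "n_trunk_layers": len(params.trunk),
        "n_decoder_layers": len(params.decoder),
        "training_log": params.training_log,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_vae(path: str) -> VAEParams:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        trunk = [(z[f"trunk_{i}_W"], z[f"trunk_{i}_b"])
                 for i in range(meta["n_trunk_layers"])]
        mu_head = (z["mu_W"], z["mu_b"])
        logvar_head = ((z["logvar_W"], z["logvar_b"])
                       if meta["variational"] else None)
        decoder = [(z[f"dec_{i}_W"], z[f"dec_{i}_b"])
                   for i in range(meta["n_decoder_layers"])]
    return VAEParams(
        arch=VAEArchitecture(**meta["arch"]),
        n_features=meta["n_features"],
        trunk=trunk,
        mu_head=mu_head,
        logvar_head=logvar_head,
        decoder=decoder,
        training_log=list(meta["training_log"]),
        trained=meta["trained"],
        variational=meta["variational"],
    )


def save_embedding(emb: LinearEmbedding, stem: str) -> None:
    """TSV loadings (features x components) + JSON metadata."""
    stem = Path(stem)
    df = pd.DataFrame(
        emb.components,
        columns=[f"{emb.kind}{i}" for i in range(emb.n_components)],
    )
    df.insert(0, "center", emb.center)
    df.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False)
    meta = {
        "kind": emb.kind,
        "n_components": emb.n_components,
        "converged": emb.converged,
        "explained_variance_ratio": (
            None if emb.explained_variance_ratio is None
            else list(map(float, emb.explained_variance_ratio))
        ),
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_embedding(stem: str) -> LinearEmbedding:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".tsv"), sep="\t")
    evr = meta["explained_variance_ratio"]
    return LinearEmbedding(
        components=df.drop(columns="center").to_numpy(),
        center=df["center"].to_numpy(),
        kind=meta["kind"],
        explained_variance_ratio=None if evr is None else np.asarray(evr),
        converged=meta["converged"],
    )


def save_minmax(params: MinMaxParams, path: str) -> None:
    pd.DataFrame(
        {"feature_id": params.feature_ids, "min": params.mins, "max": params.maxs}
    ).to_csv(path, sep="\t", index=False)


def load_minmax(path: str) -> MinMaxParams:
    df = pd.read_csv(path, sep="\t")
    return MinMaxParams(
        feature_ids=[str(f) for f in df["feature_id"]],
        mins=df["min"].to_numpy(),
        maxs=df["max"].to_numpy(),
    )
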