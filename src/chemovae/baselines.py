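"""Comparison encoders: plain autoencoder, PCA, and ICA.

The autoencoder reuses the VAE's layer plan but with a deterministic
bottleneck and reconstruction loss only (no KL term, no sampling), so any
performance difference against the VAE isolates the variational machinery.
PCA keeps the smallest number of components reaching a cumulative
explained-variance threshold (default 90%), with exact full-SVD semantics;
ICA is fastICA with the component count matched to PCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import FeatureMatrix
from .vae import VAEArchitecture, VAEParams, encode, train_vae

logger = logging.getLogger(__name__)


def train_autoencoder(data, arch: VAEArchitecture, seed: int = 0, **train_kw) -> VAEParams:
    """Train a plain autoencoder with the matched architecture.

    Identical network shapes to the corresponding VAE (same seed gives the
    same initial shared weights), but the bottleneck is deterministic and
    only the reconstruction loss is minimized.
    """
    return train_vae(data, arch, seed=seed, variational=False, **train_kw)


def ae_encode(x, params: VAEParams) -> np.ndarray:
    """Deterministic bottleneck code for one sample or a matrix."""
    if params.variational:
        raise ValueError("params belong to a VAE; use chemovae.vae.encode")
    return encode(x, params, deterministic=True).mu


@dataclass
class LinearEmbedding:
    """Fitted linear projection (PCA loadings or ICA unmixing)."""

    components: np.ndarray               # features x k
    center: np.ndarray                   # per-feature offsets
    kind: str                            # "pca" | "ica"
    explained_variance_ratio: np.ndarray | None = None
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def _values(data) -> np.ndarray:
    if isinstance(data, FeatureMatrix):
        return data.values
    return np.asarray(data, dtype=float)


def pca_fit(data, variance_threshold: float = 0.9) -> LinearEmbedding:
    """PCA keeping the smallest k with cumulative explained variance >=
    threshold; exact (full) SVD solver."""
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError(
            f"variance_threshold must be in (0, 1], got {variance_threshold}"
        )
    X = _values(data)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    full = PCA(svd_solver="full")
    full.fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(cum))
    return LinearEmbedding(
        components=full.components_[:k].T.copy(),
        center=full.mean_.copy(),
        kind="pca",
        explained_variance_ratio=full.explained_variance_ratio_[:k].copy(),
    )


def pca_transform(x, emb: LinearEmbedding) -> np.ndarray:
    if emb.kind != "pca":
        raise ValueError("embedding is not PCA")
    X = _values(x)
    return (X - emb.center) @ emb.components


def ica_fit(data, n_components: int, seed: int = 0, max_iter: int = 1000) -> LinearEmbedding:
    """fastICA with a fixed component count (matched to PCA).

    Components are canonicalized for reproducibility: each component's
    largest-magnitude loading is made positive, and components are ordered
    by explained signal power (squared norm of the mixing column, with
    unit-variance sources). Non-convergence logs a warning and returns the
    partial result flagged ``converged=False``.
    """
    X = _values(data)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, features)"
        )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica = FastICA(
            n_components=n_components, random_state=seed,
            whiten="unit-variance", max_iter=max_iter,
        )
        ica.fit(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning("fastICA did not converge in %d iterations", max_iter)

    unmix = ica.components_.copy()           # k x features
    mixing = ica.mixing_.copy()              # features x k
    # sign canonicalization on the unmixing rows
    for i in range(unmix.shape[0]):
        j = int(np.argmax(np.abs(unmix[i])))
        if unmix[i, j] < 0:
            unmix[i] *= -1.0
            mixing[:, i] *= -1.0
    power = (mixing ** 2).sum(axis=0)
    order = np.argsort(-power, kind="stable")
    return LinearEmbedding(
        components=unmix[order].T.copy(),
        center=ica.mean_.copy(),
        kind="ica",
        converged=converged,
    )


def ica_transform(x, emb: LinearEmbedding) -> np.ndarray:
    if emb.kind != "ica":
        raise ValueError("embedding is not ICA")
    X = _values(x)
    return (X - emb.center) @ emb.components


def linear_transform(x, emb: LinearEmbedding) -> np.ndarray:
    return (_values(x) - emb.center) @ emb.components
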