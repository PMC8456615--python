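"""End-to-end semi-supervised workflow glue.

Chains the stages the way the method runs in practice: variance-filter and
scale the expression data, train the encoder on the whole cohort (labeled
and unlabeled samples together), encode the labeled subset, then measure
classifier performance by replicated pooled cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import baselines
from .classification import HyperGrid
from .evaluation import CVScheme, ReplicationResult, replicated_cv
from .preprocess import build_vae_input
from .synthetic import UNLABELED, SyntheticCohort
from .vae import VAEArchitecture, encode, train_vae


@dataclass
class FeatureSets:
    """Labeled-subset design matrices per encoding method."""

    X: dict[str, np.ndarray]
    y: np.ndarray
    labeled_idx: np.ndarray
    vae_params: object = None
    ae_params: object = None


def build_feature_sets(
    cohort: SyntheticCohort,
    arch: VAEArchitecture,
    methods=("vae", "raw"),
    seed: int = 0,
    quantile: float = 0.20,
    pca_variance: float = 0.9,
    encode_deterministic: bool = False,
    **train_kw,
) -> FeatureSets:
    """Preprocess, fit the requested encoders on all samples, and return
    labeled-subset feature matrices.

    The VAE/AE are trained on the full cohort ignoring labels (the
    semi-supervised step); the labeled samples are then encoded — for the
    VAE with a single reparameterized draw per tumor unless
    ``encode_deterministic`` is set.
    """
    X01, _, _ = build_vae_input(
        cohort.counts_matrix(), cohort.abundance_matrix(),
        cohort.type_of, quantile=quantile,
    )
    labeled = np.flatnonzero(cohort.label_of != UNLABELED)
    y = cohort.label_of[labeled]
    Xl = X01.values[labeled]
    out: dict[str, np.ndarray] = {}
    vae_params = ae_params = None
    for method in methods:
        if method == "raw":
            out["raw"] = Xl
        elif method == "vae":
            vae_params = train_vae(X01, arch, seed=seed, **train_kw)
            enc = encode(Xl, vae_params, seed=seed + 1,
                         deterministic=encode_deterministic)
            out["vae"] = enc.z
        elif method == "ae":
            ae_params = baselines.train_autoencoder(X01, arch, seed=seed, **train_kw)
            out["ae"] = baselines.ae_encode(Xl, ae_params)
        elif method == "pca":
            emb = baselines.pca_fit(X01.values, variance_threshold=pca_variance)
            out["pca"] = baselines.pca_transform(Xl, emb)
        elif method == "ica":
            emb_p = baselines.pca_fit(X01.values, variance_threshold=pca_variance)
            emb = baselines.ica_fit(X01.values, emb_p.n_components, seed=seed)
            out["ica"] = baselines.ica_transform(Xl, emb)
        elif method == "latent_truth":
            out["latent_truth"] = cohort.latent_truth[labeled]
        else:
            raise ValueError(f"unknown feature method {method!r}")
    return FeatureSets(X=out, y=y, labeled_idx=labeled,
                       vae_params=vae_params, ae_params=ae_params)


def evaluate_feature_sets(
    feats: FeatureSets,
    scheme: CVScheme,
    grid: HyperGrid,
    inner_folds: int = 5,
    keep_models: bool = False,
) -> ReplicationResult:
    return replicated_cv(
        feats.X, feats.y, scheme, grid,
        inner_folds=inner_folds, keep_models=keep_models,
    )
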