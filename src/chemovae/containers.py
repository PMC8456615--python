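"""Shared in-memory containers and on-disk matrix dialect.

The package moves expression data around as a :class:`FeatureMatrix`:
samples in rows, features (genes or latent dimensions) in columns, plus a
``state`` tag recording where the matrix sits in the preprocessing pipeline
(``counts`` → ``log_norm`` → ``minmax``, with ``abundance`` as the
length-normalized side channel used only for variance filtering).

On disk, expression matrices follow the common portal layout: genes as rows,
first column the gene id, header row the sample ids, tab-separated and
optionally gzip-compressed (by ``.gz`` suffix).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

VALID_STATES = ("counts", "log_norm", "minmax", "abundance", "latent")


@dataclass
class FeatureMatrix:
    """Samples x features numeric matrix with provenance state.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
    sample_ids, feature_ids : ordered identifiers matching the axes
    state : one of ``counts``, ``log_norm``, ``minmax``, ``abundance``,
        ``latent``
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    state: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.feature_ids) != m:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {m} columns"
            )
        if len(set(self.feature_ids)) != m:
            raise ValueError("feature_ids must be unique")
        if self.state not in VALID_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if np.isnan(self.values).any():
            raise ValueError("FeatureMatrix may not contain missing values")
        if self.state == "minmax":
            if self.values.min(initial=0.0) < -1e-12 or self.values.max(initial=0.0) > 1 + 1e-12:
                raise ValueError("state='minmax' requires values in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def subset_features(self, ids: Sequence[str]) -> "FeatureMatrix":
        pos = {g: i for i, g in enumerate(self.feature_ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"features not present: {missing[:5]}")
        cols = [pos[g] for g in ids]
        return replace(
            self, values=self.values[:, cols], feature_ids=list(ids)
        )

    def to_frame(self) -> pd.DataFrame:
        """Genes-as-rows DataFrame in the on-disk orientation."""
        return pd.DataFrame(
            self.values.T, index=self.feature_ids, columns=self.sample_ids
        )


def write_matrix_tsv(fm: FeatureMatrix, path: str) -> None:
    """Write in the portal dialect (genes as rows, gzip if path ends .gz)."""
    df = fm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str, state: str = "counts") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix(
        values=df.to_numpy(dtype=float).T,
        sample_ids=[str(c) for c in df.columns],
        feature_ids=[str(i) for i in df.index],
        state=state,
    )
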