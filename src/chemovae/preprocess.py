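"""Feature construction for transcriptome encoders.

The pipeline mirrors standard portal-style expression handling:

1. ``log_total_count_normalize`` — per-sample total-count normalization to a
   fixed target depth followed by log2(1+C).
2. ``mad_per_gene`` / ``select_top_variance_union`` — high-variance gene
   filtering by median absolute deviation of length-normalized abundance
   (FPKM-like), taking the top quantile per group (e.g. per cancer type) and
   merging the selections across groups.
3. ``minmax_fit`` / ``minmax_apply`` — per-feature min-max scaling into
   [0, 1], the input contract of the variational autoencoder.

MAD uses the 1.4826 normal-consistency constant (the R stats default).
Min-max parameters are fitted on the full encoder-training cohort (labeled
and unlabeled samples together) and reused downstream — an intentional
transductive step of the semi-supervised design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix

MAD_SCALE = 1.4826


@dataclass
class GeneFilterResult:
    """Outcome of top-variance gene selection."""

    selected_ids: list[str]
    mad_scores: dict[str, np.ndarray]   # group -> per-gene MAD
    per_group_selected: dict[str, list[str]]
    quantile: float


@dataclass
class MinMaxParams:
    feature_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray


def log_total_count_normalize(
    counts: FeatureMatrix, target_depth: float | None = None
) -> FeatureMatrix:
    """Total-count normalize each sample to ``target_depth`` then log2(1+C).

    With ``target_depth=None`` the cohort median library size is used, so
    relative within-sample structure is preserved while sequencing depth is
    equalized.
    """
    if counts.state != "counts":
        raise ValueError(f"expected state='counts', got {counts.state!r}")
    v = counts.values
    if (v < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = v.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total counts: "
            f"{[counts.sample_ids[i] for i in zero[:5]]}"
        )
    if target_depth is None:
        target_depth = float(np.median(totals))
    scaled = v / totals[:, None] * target_depth
    return FeatureMatrix(
        np.log2(1.0 + scaled), counts.sample_ids, counts.feature_ids, "log_norm"
    )


def mad_per_gene(abundance: FeatureMatrix) -> np.ndarray:
    """Per-gene median absolute deviation across samples, scaled by 1.4826."""
    if abundance.n_samples < 2:
        raise ValueError("MAD requires at least 2 samples")
    # R's mad() default constant is exactly 1.4826 (scipy's scale="normal"
    # would use 1/qnorm(0.75) = 1.4826022... instead)
    return stats.median_abs_deviation(abundance.values, axis=0, scale=1.0 / MAD_SCALE)


def select_top_variance_union(
    abundance_by_group: dict[str, FeatureMatrix], quantile: float = 0.20
) -> GeneFilterResult:
    """Top ``quantile`` most-MAD-variable genes per group, merged across groups.

    Within each group the ceil(quantile * n_genes) highest-MAD genes are
    taken (MAD ties at the boundary are kept inclusively); the union across
    groups is returned in lexicographic gene-id order so downstream feature
    indices are reproducible.
    """
    if not abundance_by_group:
        raise ValueError("no groups given")
    if not 0.0 < quantile <= 1.0:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    groups = list(abundance_by_group)
    universe = abundance_by_group[groups[0]].feature_ids
    mad_scores: dict[str, np.ndarray] = {}
    per_group: dict[str, list[str]] = {}
    union: set[str] = set()
    for g in groups:
        fm = abundance_by_group[g]
        if fm.n_samples == 0 or fm.n_features == 0:
            raise ValueError(f"group {g!r} is empty")
        if fm.feature_ids != universe:
            raise ValueError(f"group {g!r} does not share the gene universe")
        scores = mad_per_gene(fm)
        mad_scores[g] = scores
        k = math.ceil(quantile * fm.n_features)
        # inclusive threshold: keep everything tied with the k-th score
        thresh = np.sort(scores)[::-1][k - 1]
        sel = [fid for fid, s in zip(fm.feature_ids, scores) if s >= thresh]
        per_group[g] = sel
        union.update(sel)
    return GeneFilterResult(
        selected_ids=sorted(union),
        mad_scores=mad_scores,
        per_group_selected=per_group,
        quantile=quantile,
    )


def minmax_fit(reference: FeatureMatrix) -> MinMaxParams:
    """Per-feature (min, max) on the stated reference cohort."""
    return MinMaxParams(
        feature_ids=list(reference.feature_ids),
        mins=reference.values.min(axis=0),
        maxs=reference.values.max(axis=0),
    )


def minmax_apply(x: FeatureMatrix, params: MinMaxParams) -> FeatureMatrix:
    """(v - min) / (max - min), clipped to [0, 1]; constant features map to 0."""
    if params is None or params.mins is None:
        raise ValueError("min-max parameters are not fitted")
    if x.feature_ids != params.feature_ids:
        raise ValueError("feature ids do not match the fitted parameters")
    span = params.maxs - params.mins
    out = np.zeros_like(x.values)
    ok = span > 0
    out[:, ok] = (x.values[:, ok] - params.mins[ok]) / span[ok]
    np.clip(out, 0.0, 1.0, out=out)
    return FeatureMatrix(out, x.sample_ids, x.feature_ids, "minmax")


def write_filter_tsv(
    result: GeneFilterResult, path: str, feature_ids: list[str]
) -> None:
    """Two-column TSV (gene id, max MAD across groups) for the selected genes."""
    stacked = np.vstack(list(result.mad_scores.values())).max(axis=0)
    score_of = dict(zip(feature_ids, stacked))
    pd.DataFrame(
        {"gene_id": result.selected_ids,
         "mad": [score_of[g] for g in result.selected_ids]}
    ).to_csv(path, sep="\t", index=False)


def build_vae_input(
    counts: FeatureMatrix,
    abundance: FeatureMatrix,
    groups: np.ndarray,
    quantile: float = 0.20,
    target_depth: float | None = None,
) -> tuple[FeatureMatrix, GeneFilterResult, MinMaxParams]:
    """Full feature path: filter genes on abundance per group, log-normalize
    counts, min-max scale on the whole cohort. Returns the [0,1] matrix, the
    filter result and the fitted scaling parameters."""
    groups = np.asarray(groups)
    by_group = {
        str(g): abundance.subset_samples(np.flatnonzero(groups == g))
        for g in np.unique(groups)
    }
    filt = select_top_variance_union(by_group, quantile=quantile)
    logn = log_total_count_normalize(counts, target_depth=target_depth)
    logn = logn.subset_features(filt.selected_ids)
    params = minmax_fit(logn)
    return minmax_apply(logn, params), filt, params
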