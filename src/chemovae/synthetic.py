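"""Synthetic tumor-cohort generator.

Emulates the statistical structure the semi-supervised pipeline assumes:
cancer-type clusters in a low-dimensional latent space, a fixed nonlinear
map into a high-dimensional nonnegative gene space, overdispersed
(negative-binomial) sequencing counts around those means, a partially
labeled cohort, and a binary chemotherapy-response label carried by a small
subset of latent directions through a logistic link.

Defaults describe the canonical study cohort used throughout the test
harness: 3 tumor types x 200 samples, 300 genes, one third of samples
labeled, a 2:1 responding/progressive balance, and a response signal of
standardized effect 2.0 on 3 of 10 latent directions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, softplus

from .containers import FeatureMatrix, write_matrix_tsv

UNLABELED = -1

# Clinical vocabulary of the two annotation dialects (see `labeling`).
XENA_RESPONDED = ["Complete response", "Partial response"]
XENA_PROGRESSIVE = [
    "Radiographic progressive disease",
    "Clinical progressive disease",
    "Stable disease",
]
XENA_COLUMNS = ["submitter_id.samples", "therapy_type", "measure_of_response"]
CBIO_COLUMNS = ["Sample_ID", "Disease.Free.Status", "Pharmaceutical.Therapy.Indicator"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    noise_sd is the within-cluster standard deviation in latent space;
    cluster centers are standard-normal draws, so small noise_sd means
    well-separated tumor types.
    """

    n_types: int = 3
    samples_per_type: int = 200
    n_genes: int = 300
    latent_dim_true: int = 10
    labeled_fraction: float = 1.0 / 3.0
    balance_ratio: float = 2.0
    signal_dims: int = 3
    signal_strength: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0
    nb_dispersion: float = 0.1  # NB variance = mu + dispersion * mu^2
    mean_library_size: float = 5e4

    def validate(self) -> None:
        for name in ("n_types", "samples_per_type", "n_genes",
                     "latent_dim_true", "signal_dims"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ValueError(
                f"labeled_fraction must be in (0, 1], got {self.labeled_fraction}"
            )
        if not self.balance_ratio > 0:
            raise ValueError(f"balance_ratio must be > 0, got {self.balance_ratio}")
        if self.signal_dims > self.latent_dim_true:
            raise ValueError(
                "signal_dims must not exceed latent_dim_true "
                f"({self.signal_dims} > {self.latent_dim_true})"
            )
        if self.signal_strength < 0:
            raise ValueError(f"signal_strength must be >= 0, got {self.signal_strength}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class SyntheticCohort:
    """A generated cohort; counts/abundance are genes x samples."""

    counts: np.ndarray
    abundance: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    type_of: np.ndarray          # int per sample
    label_of: np.ndarray         # 0 responded, 1 progressive, -1 unlabeled
    latent_truth: np.ndarray     # samples x latent_dim_true
    spec: SyntheticSpec = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def counts_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(self.counts.T, self.sample_ids, self.gene_ids, "counts")

    def abundance_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(self.abundance.T, self.sample_ids, self.gene_ids, "abundance")


def _solve_intercept(score: np.ndarray, strength: float, ratio: float) -> float:
    """Intercept b so that mean sigmoid(b + strength*score) = P(progressive)."""
    target = 1.0 / (1.0 + ratio)  # P(y=1) when responding/progressive = ratio

    def gap(b: float) -> float:
        return float(np.mean(expit(b + strength * score))) - target

    return brentq(gap, -50.0, 50.0, xtol=1e-12)


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw a cohort. Deterministic given spec (including its seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_types * spec.samples_per_type
    k, m = spec.latent_dim_true, spec.n_genes

    # latent cluster structure
    centers = rng.normal(0.0, 1.0, size=(spec.n_types, k))
    type_of = np.repeat(np.arange(spec.n_types), spec.samples_per_type)
    latent = centers[type_of] + rng.normal(0.0, spec.noise_sd, size=(n, k))

    # fixed nonlinear map latent -> nonnegative gene means
    w_map = rng.normal(0.0, 1.0 / np.sqrt(k), size=(k, m))
    b_map = rng.normal(0.0, 1.0, size=m)
    gene_mean = softplus(latent @ w_map + b_map)  # n x m, > 0

    # scale each sample to a plausible library size, then NB counts
    lib = rng.lognormal(np.log(spec.mean_library_size), 0.3, size=n)
    rate = gene_mean / gene_mean.sum(axis=1, keepdims=True) * lib[:, None]
    r = 1.0 / spec.nb_dispersion
    p = r / (r + rate)
    counts = rng.negative_binomial(r, p).astype(np.int64).T  # genes x samples

    # FPKM-like abundance with random per-gene lengths
    lengths_bp = rng.uniform(500.0, 5000.0, size=m)
    totals = counts.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    abundance = counts * 1e9 / (lengths_bp[:, None] * totals[None, :])

    # partial labeling with a logistic response signal on the first
    # signal_dims latent coordinates
    w_sig = rng.normal(0.0, 1.0, size=spec.signal_dims)
    w_sig /= np.linalg.norm(w_sig)
    raw = latent[:, : spec.signal_dims] @ w_sig
    score = (raw - raw.mean()) / (raw.std() if raw.std() > 0 else 1.0)
    b0 = _solve_intercept(score, spec.signal_strength, spec.balance_ratio)
    p_prog = expit(b0 + spec.signal_strength * score)

    n_labeled = int(round(spec.labeled_fraction * n))
    labeled_idx = rng.choice(n, size=n_labeled, replace=False)
    label_of = np.full(n, UNLABELED, dtype=np.int64)
    label_of[labeled_idx] = (rng.random(n_labeled) < p_prog[labeled_idx]).astype(np.int64)

    gene_ids = [f"G{i:05d}" for i in range(m)]
    sample_ids = [f"S{i:05d}" for i in range(n)]
    return SyntheticCohort(
        counts=counts,
        abundance=abundance,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        type_of=type_of,
        label_of=label_of,
        latent_truth=latent,
        spec=spec,
    )


def _maybe_case(rng: np.random.Generator, s: str) -> str:
    """Randomize capitalization (portal exports are inconsistent)."""
    u = rng.random()
    if u < 0.3:
        return s.lower()
    if u < 0.4:
        return s.upper()
    return s


def generate_clinical_table(cohort: SyntheticCohort, dialect: str = "xena") -> pd.DataFrame:
    """Emit a clinical annotation table in the Xena or cBioPortal dialect.

    Labeled samples get chemotherapy records whose response vocabulary maps
    back to their label; unlabeled samples get either empty response fields
    or a non-chemotherapy record (which the labeling rules must ignore).
    """
    if dialect not in ("xena", "cbioportal"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if cohort.label_of is None:
        raise ValueError("cohort has no labels")
    rng = np.random.default_rng(
        (cohort.spec.seed if cohort.spec is not None else 0) + 104729
    )
    rows = []
    for sid, y in zip(cohort.sample_ids, cohort.label_of):
        if dialect == "xena":
            if y == 0:
                resp = _maybe_case(rng, str(rng.choice(XENA_RESPONDED)))
                rows.append((sid, _maybe_case(rng, "Chemotherapy"), resp))
            elif y == 1:
                resp = _maybe_case(rng, str(rng.choice(XENA_PROGRESSIVE)))
                rows.append((sid, _maybe_case(rng, "Chemotherapy"), resp))
            else:
                if rng.random() < 0.3:
                    # treated, but not with chemotherapy: must stay unlabeled
                    resp = _maybe_case(
                        rng, str(rng.choice(XENA_RESPONDED + XENA_PROGRESSIVE))
                    )
                    rows.append((sid, "Hormone Therapy", resp))
                else:
                    rows.append((sid, "", ""))
        else:
            if y == 0:
                rows.append((sid, _maybe_case(rng, "DiseaseFree"), _maybe_case(rng, "Yes")))
            elif y == 1:
                rows.append((sid, _maybe_case(rng, "Recurred/Progressed"), _maybe_case(rng, "Yes")))
            else:
                if rng.random() < 0.3:
                    status = _maybe_case(
                        rng, str(rng.choice(["DiseaseFree", "Recurred/Progressed"]))
                    )
                    rows.append((sid, status, "No"))
                else:
                    rows.append((sid, "", ""))
    cols = XENA_COLUMNS if dialect == "xena" else CBIO_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def write_cohort(cohort: SyntheticCohort, outdir: str) -> None:
    """Write counts/abundance (gzip TSV), both clinical tables, labels and a
    JSON sidecar with the generating spec."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(cohort.counts_matrix(), str(out / "counts.tsv.gz"))
    write_matrix_tsv(cohort.abundance_matrix(), str(out / "abundance.tsv.gz"))
    for dialect in ("xena", "cbioportal"):
        generate_clinical_table(cohort, dialect).to_csv(
            out / f"clinical_{dialect}.tsv", sep="\t", index=False
        )
    pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "type": cohort.type_of,
            "label": cohort.label_of,
        }
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "spec.json", "w") as fh:
        json.dump(asdict(cohort.spec), fh, indent=2)
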