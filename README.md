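# chemovae

Semi-supervised prediction of tumor response to chemotherapy from bulk
RNA-seq transcriptomes.

## The problem

Clinical response labels (responded vs. progressive disease under
chemotherapy) exist for only a minority of tumors in most cohorts, while
transcriptomes exist for many more. `chemovae` exploits the unlabeled
majority: a variational autoencoder (VAE) is trained on *all*
transcriptomes to learn a low-dimensional latent representation, each
labeled tumor is encoded into that space, and a gradient-boosted tree
classifier (XGBoost) is trained on the latent encodings of the labeled
subset. The package is aimed at computational oncology groups who want a
reproducible, desk-scale implementation of this VAE→XGBoost recipe with
its full measurement harness.

## The model

The encoder maps a min-max-scaled expression vector **x** ∈ [0,1]^m to a
diagonal-Gaussian latent variable

&nbsp;&nbsp;**Z**|**x** ~ N(μ(**x**), diag(σ²(**x**))),&nbsp;&nbsp;
z = μ + √σ² ⊙ ε,&nbsp; ε ~ N(0, I),

and the mirrored decoder g maps z back to [0,1]^m. Fitting minimizes, over
tumors t,

&nbsp;&nbsp;Σ_t [ (1/J) Σ_j ‖**x**_t − g(μ_t + √σ²_t ⊙ ε_j)‖₁
  + ½ Σ_i (μ_i² + σ_i² − log σ_i² − 1) ],

i.e. an L1 reconstruction loss (L2 and binary cross-entropy selectable)
plus the closed-form KL divergence from the standard-normal prior, by Adam
(lr 2·10⁻³, β₁ 0.9, β₂ 0.999). A single sampled z per tumor is the feature
vector handed to the classifier. Upstream: genes are filtered to the
top-20% most variable by median absolute deviation of FPKM-like abundance
(per cancer type, merged by union), log2(1+C) total-count normalized, and
min-max scaled. Downstream: performance is measured by 30 replications of
pooled five-fold cross-validation (AUROC/AUPRC), with Welch's t-tests on
logit-transformed replication values for method comparisons.

A synthetic-cohort generator (latent tumor-type clusters → softplus gene
means → negative-binomial counts, plus partially-observed logistic
response labels) makes every stage testable without downloading anything.
See `docs/methods.md` for the full model description, parameter defaults,
and design decisions.

## Worked example

```python
import chemovae as cv
from chemovae.vae import VAEArchitecture

# 600 synthetic tumors (3 types), 300 genes, 200 labeled at 2:1 balance
cohort = cv.generate_cohort(cv.SyntheticSpec(seed=11))

arch = VAEArchitecture(latent_dim=10, n_layers=2, loss_kind="l1")
feats = cv.build_feature_sets(
    cohort, arch, methods=("vae", "raw"), seed=0,
    encode_deterministic=True, max_epochs=400, patience=30,
)
result = cv.evaluate_feature_sets(
    feats,
    cv.CVScheme(folds=5, replications=5, seed_base=100),
    cv.HyperGrid("gbdt", budget=50),
)
print(cv.build_comparison_table(result, reference="vae"))
```

prints

```
method  mean_auroc  mean_auprc  p_vs_vae  best
   vae      0.8361      0.7531       NaN False
   raw      0.8519      0.7569    0.0505  True
```

Read: over 5 replications of pooled five-fold CV on the 200 labeled
tumors, the 10-dimensional VAE encoding carries essentially the same
response signal as the full 94-gene filtered expression matrix (mean AUROC
0.836 vs 0.852, where 0.5 is chance; the Welch p-value on logit-AUROC is
borderline). On a panel this small the fully-supervised baseline is
competitive — the latent encoding's advantage grows in the regime it is
designed for, where the gene dimension far exceeds the labeled sample
count. AUPRC should be read against the chance baseline of the
progressive-class prevalence (here 0.34).

The same pipeline is scriptable from a shell:

```sh
chemovae simulate --seed 11 --out scratch/cohort
chemovae evaluate --cohort scratch/cohort --methods vae,raw --reps 5 \
    --grid-budget 50 --out scratch/results
chemovae label --cohort scratch/cohort --dialect xena --out scratch/labels.tsv
```

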