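"""Measurement harness: replicated cross-validation, AUROC/AUPRC,
logit-Welch comparisons, comparison tables and 2-D embedding diagnostics.

The protocol is 30 replications of stratified five-fold cross-validation.
Within each replication the out-of-fold prediction scores are pooled across
the five folds — every labeled sample is scored exactly once, by the model
from the fold in which it was held out — and a single AUROC and AUPRC are
computed from the pooled scores. Hyperparameter tuning runs inside each
training fold, never on held-out data. Replication r derives its folds from
seed_base + r.

Feature-set comparisons use two-tailed Welch's t-tests on logit-transformed
replication values; values are clamped away from {0, 1} before the logit so
a perfect replication does not produce infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .classification import HyperGrid, grid_search_fit, predict_scores


@dataclass
class CVScheme:
    folds: int = 5
    replications: int = 30
    seed_base: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


@dataclass
class ReplicationResult:
    """Per-replication pooled metrics and out-of-fold scores per feature set."""

    auroc: dict[str, np.ndarray]             # method -> (replications,)
    auprc: dict[str, np.ndarray]
    oof_scores: dict[str, np.ndarray]        # method -> (replications, n)
    best_params: dict[str, list] = field(default_factory=dict)
    models: dict[str, list] = field(default_factory=dict)
    n_pairs: int = 0                         # positives x negatives

    def methods(self) -> list[str]:
        return list(self.auroc)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.methods():
            for r, (a, p) in enumerate(zip(self.auroc[m], self.auprc[m])):
                rows.append((m, r, a, p))
        return pd.DataFrame(rows, columns=["method", "replication", "auroc", "auprc"])


def auroc(labels, scores) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve, trapezoidal over the attained
    operating points.

    The curve is extended horizontally from the highest-threshold attained
    point to recall 0 (rather than pinning an artificial precision-1
    anchor), so that uninformative tied scores give an area equal to the
    class prevalence.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if (labels == 1).sum() == 0:
        raise ValueError("AUPRC needs at least one positive")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # precision_recall_curve appends the conventional (recall 0, precision 1)
    # endpoint with no corresponding threshold; drop it and continue the
    # leftmost attained precision to recall 0 instead.
    precision, recall = precision[:-1], recall[:-1]
    precision = np.concatenate([[precision[-1]], precision[::-1]])
    recall = np.concatenate([[0.0], recall[::-1]])
    return float(_sk_auc(recall, precision))


@dataclass
class WelchResult:
    mean_a: float
    mean_b: float
    t: float
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.mean_a, self.mean_b, self.p))


def logit_welch_compare(group_a, group_b, n_pairs: int | None = None) -> WelchResult:
    """Two-tailed Welch's t-test on logit-transformed metric values.

    Values are clamped to [eps, 1-eps] with eps = 1/(2*n_pairs) when the
    number of positive-negative pairs is known (1e-6 otherwise) before the
    logit. Two identical zero-variance groups return p=1, flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    eps = 1.0 / (2.0 * n_pairs) if n_pairs else 1e-6
    la = logit(np.clip(a, eps, 1.0 - eps))
    lb = logit(np.clip(b, eps, 1.0 - eps))
    if np.ptp(la) == 0 and np.ptp(lb) == 0:
        if la[0] == lb[0]:
            return WelchResult(float(a.mean()), float(b.mean()), 0.0, 1.0, True)
    t, p = stats.ttest_ind(la, lb, equal_var=False)
    if np.isnan(p):
        return WelchResult(float(a.mean()), float(b.mean()), 0.0, 1.0, True)
    return WelchResult(float(a.mean()), float(b.mean()), float(t), float(p))


def replicated_cv(
    X_by_featureset: dict[str, np.ndarray],
    y,
    scheme: CVScheme,
    grid: HyperGrid,
    inner_folds: int = 5,
    keep_models: bool = False,
) -> ReplicationResult:
    """Replications of pooled k-fold CV for each feature set.

    All feature sets share the same labels and, within a replication, the
    same fold assignment, so per-replication metric vectors are paired
    across methods.
    """
    y = np.asarray(y)
    n = len(y)
    if n < scheme.folds:
        raise ValueError("fewer labeled samples than folds")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    for name, X in X_by_featureset.items():
        if len(X) != n:
            raise ValueError(f"feature set {name!r} has {len(X)} rows for {n} labels")

    methods = list(X_by_featureset)
    res = ReplicationResult(
        auroc={m: np.empty(scheme.replications) for m in methods},
        auprc={m: np.empty(scheme.replications) for m in methods},
        oof_scores={m: np.empty((scheme.replications, n)) for m in methods},
        best_params={m: [] for m in methods},
        models={m: [] for m in methods},
        n_pairs=int((y == 1).sum() * (y == 0).sum()),
    )
    for r in range(scheme.replications):
        fold_seed = (scheme.seed_base + r) % (2 ** 31 - 1)
        if scheme.stratified:
            splitter = StratifiedKFold(scheme.folds, shuffle=True, random_state=fold_seed)
        else:
            splitter = KFold(scheme.folds, shuffle=True, random_state=fold_seed)
        folds = list(splitter.split(np.zeros(n), y))
        for tr, te in folds:
            if len(np.unique(y[tr])) < 2:
                raise ValueError(
                    "a training fold contains a single class; enable "
                    "stratified folds"
                )
        for m in methods:
            X = np.asarray(X_by_featureset[m], dtype=float)
            oof = np.full(n, np.nan)
            for tr, te in folds:
                fit = grid_search_fit(
                    X[tr], y[tr], grid, inner_folds=inner_folds, seed=fold_seed
                )
                oof[te] = predict_scores(fit.model, X[te])
                res.best_params[m].append(fit.best_params)
                if keep_models:
                    res.models[m].append(fit.model)
            assert not np.isnan(oof).any()
            res.oof_scores[m][r] = oof
            res.auroc[m][r] = auroc(y, oof)
            res.auprc[m][r] = auprc(y, oof)
    return res


@dataclass
class ComparisonTable:
    frame: pd.DataFrame
    reference: str

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        return self.frame.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def build_comparison_table(
    result: ReplicationResult, reference: str = "vae", metric: str = "auroc"
) -> ComparisonTable:
    """Per-method mean AUROC/AUPRC with Welch p-values against a reference
    method on the logit scale; the best mean metric is flagged (ties share
    the flag)."""
    methods = result.methods()
    if reference not in methods:
        reference = methods[0]
    values = getattr(result, metric)
    lengths = {len(values[m]) for m in methods}
    if len(lengths) != 1:
        raise ValueError("replication counts differ across methods")
    rows = []
    means = {m: float(np.mean(values[m])) for m in methods}
    best = max(means.values())
    for m in methods:
        if m == reference:
            p = np.nan
        else:
            p = logit_welch_compare(
                values[reference], values[m], n_pairs=result.n_pairs
            ).p
        rows.append(
            {
                "method": m,
                "mean_auroc": float(np.mean(result.auroc[m])),
                "mean_auprc": float(np.mean(result.auprc[m])),
                f"p_vs_{reference}": p,
                "best": np.isclose(means[m], best),
            }
        )
    return ComparisonTable(pd.DataFrame(rows), reference)


def embed_2d(X, method: str = "tsne", seed: int = 0, **params) -> np.ndarray:
    """2-D embedding diagnostics with the published defaults.

    t-SNE: init='pca', perplexity=20, learning_rate=300, 400 iterations.
    UMAP: n_neighbors=50, min_dist=0.3, metric='euclidean'.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = params.pop("perplexity", 20)
        if n < 3 * perplexity:
            raise ValueError(
                f"t-SNE with perplexity {perplexity} needs at least "
                f"{3 * perplexity} samples, got {n}"
            )
        tsne = TSNE(
            n_components=2, init="pca", perplexity=perplexity,
            learning_rate=params.pop("learning_rate", 300),
            max_iter=params.pop("n_iter", 400),
            random_state=seed, **params,
        )
        return np.asarray(tsne.fit_transform(X))
    if method == "umap":
        import umap

        n_neighbors = params.pop("n_neighbors", 50)
        if n <= n_neighbors:
            raise ValueError(
                f"UMAP with n_neighbors {n_neighbors} needs more than "
                f"{n_neighbors} samples, got {n}"
            )
        reducer = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors,
            min_dist=params.pop("min_dist", 0.3),
            metric=params.pop("metric", "euclidean"),
            random_state=seed, **params,
        )
        return np.asarray(reducer.fit_transform(X))
    raise ValueError(f"unknown embedding method {method!r}")
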