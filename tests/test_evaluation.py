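"""Measurement harness: metrics, Welch comparisons, replicated CV,
embeddings."""

import numpy as np
import pytest
from scipy.special import logit as sp_logit
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import chemovae as cv
from chemovae.evaluation import WelchResult


def brute_force_auroc(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestAUROC:
    def test_perfect_ranking(self):
        assert cv.auroc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.1]) == 1.0

    def test_worked_example(self):
        assert cv.auroc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]) == pytest.approx(0.75)

    def test_score_reversal_symmetry(self, rng):
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        s = rng.random(30)
        assert cv.auroc(y, -s) == pytest.approx(1 - cv.auroc(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            cv.auroc([1, 1], [0.5, 0.4])

    def test_brute_force_oracle_100_instances(self, rng):
        """Pairwise-comparison oracle agreement to 1e-12, ties included."""
        for _ in range(100):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            s = np.round(rng.random(n), 2)  # rounding forces occasional ties
            assert cv.auroc(y, s) == pytest.approx(
                brute_force_auroc(y, s), abs=1e-12
            )


class TestAUPRC:
    def test_perfect_ranking_is_one(self):
        assert cv.auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)

    def test_tied_scores_give_prevalence(self):
        y = [1, 0, 0, 0]
        assert cv.auprc(y, [0.5] * 4) == pytest.approx(0.25)

    def test_random_scores_near_prevalence(self, rng):
        vals = []
        for _ in range(300):
            y = (rng.random(60) < 0.3).astype(int)
            if y.sum() == 0:
                continue
            vals.append(cv.auprc(y, rng.random(60)))
        assert abs(np.mean(vals) - 0.3) < 0.05

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cv.auprc([0, 0], [0.1, 0.9])


class TestLogitWelch:
    def test_identical_groups_p_one(self):
        r = cv.logit_welch_compare([0.7, 0.7], [0.7, 0.7])
        assert r.p == 1.0 and r.degenerate

    def test_logit_values(self):
        assert sp_logit(0.5) == 0.0
        assert sp_logit(0.75) == pytest.approx(np.log(3))

    def test_matches_scipy_on_transformed_values(self, rng):
        from scipy import stats

        a = rng.uniform(0.55, 0.75, 30)
        b = rng.uniform(0.5, 0.7, 30)
        r = cv.logit_welch_compare(a, b)
        t, p = stats.ttest_ind(sp_logit(a), sp_logit(b), equal_var=False)
        assert r.p == pytest.approx(p)

    def test_clamp_handles_perfect_replications(self):
        r = cv.logit_welch_compare([1.0, 0.99, 1.0], [0.6, 0.62, 0.58],
                                   n_pairs=50)
        assert np.isfinite(r.t) and 0 < r.p < 0.05

    def test_power_on_separated_groups(self, rng):
        """N(0.7, 0.01) vs N(0.6, 0.01), n=30: p < 0.01 nearly always."""
        hits = 0
        for _ in range(100):
            a = np.clip(rng.normal(0.7, 0.01, 30), 0.01, 0.99)
            b = np.clip(rng.normal(0.6, 0.01, 30), 0.01, 0.99)
            if cv.logit_welch_compare(a, b).p < 0.01:
                hits += 1
        assert hits >= 95

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="2 values"):
            cv.logit_welch_compare([0.5], [0.6, 0.7])


@pytest.fixture(scope="module")
def tiny_cv_setup():
    rng = np.random.default_rng(42)
    n = 40
    X = rng.normal(size=(n, 5))
    y = (X[:, 0] + rng.normal(scale=0.8, size=n) > 0).astype(int)
    grid = cv.HyperGrid(
        "gbdt", grid={"n_estimators": [10], "max_depth": [2]},
        budget="exhaustive",
    )
    return X, y, grid


class TestReplicatedCV:
    def test_pooled_vector_covers_every_sample_once(self, tiny_cv_setup):
        X, y, grid = tiny_cv_setup
        scheme = cv.CVScheme(folds=5, replications=2, seed_base=7)
        res = cv.replicated_cv({"m": X}, y, scheme, grid)
        assert res.oof_scores["m"].shape == (2, len(y))
        assert np.isfinite(res.oof_scores["m"]).all()

    def test_replication_counts(self, tiny_cv_setup):
        X, y, grid = tiny_cv_setup
        res = cv.replicated_cv(
            {"a": X, "b": X + 1}, y, cv.CVScheme(5, 3, 0), grid
        )
        for m in ("a", "b"):
            assert len(res.auroc[m]) == 3 and len(res.auprc[m]) == 3

    def test_null_data_auroc_near_half(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        grid = cv.HyperGrid(
            "gbdt", grid={"n_estimators": [5], "max_depth": [2]},
            budget="exhaustive",
        )
        res = cv.replicated_cv({"m": X}, y, cv.CVScheme(5, 10, 3), grid)
        assert 0.4 <= res.auroc["m"].mean() <= 0.6

    def test_deterministic_given_seed_base(self, tiny_cv_setup):
        X, y, grid = tiny_cv_setup
        a = cv.replicated_cv({"m": X}, y, cv.CVScheme(5, 2, 11), grid)
        b = cv.replicated_cv({"m": X}, y, cv.CVScheme(5, 2, 11), grid)
        np.testing.assert_array_equal(a.auroc["m"], b.auroc["m"])

    def test_misaligned_features_rejected(self, tiny_cv_setup):
        X, y, grid = tiny_cv_setup
        with pytest.raises(ValueError, match="rows"):
            cv.replicated_cv({"m": X[:-1]}, y, cv.CVScheme(5, 1, 0), grid)


class TestComparisonTable:
    def test_identical_methods_tie(self, tiny_cv_setup):
        X, y, grid = tiny_cv_setup
        res = cv.replicated_cv({"vae": X, "copy": X}, y, cv.CVScheme(5, 3, 0), grid)
        table = cv.build_comparison_table(res, reference="vae")
        df = table.frame
        assert df["best"].all()
        p = df.loc[df.method == "copy", "p_vs_vae"].item()
        assert p == 1.0

    def test_mean_column_matches_replications(self, tiny_cv_setup):
        X, y, grid = tiny_cv_setup
        res = cv.replicated_cv({"vae": X}, y, cv.CVScheme(5, 3, 0), grid)
        table = cv.build_comparison_table(res, reference="vae")
        assert table.frame["mean_auroc"].iloc[0] == pytest.approx(
            res.auroc["vae"].mean(), abs=1e-12
        )

    def test_planted_advantage_flagged_best(self, rng):
        n = 60
        signal = rng.normal(size=(n, 3))
        y = (signal[:, 0] > 0).astype(int)
        noise = rng.normal(size=(n, 3))
        grid = cv.HyperGrid(
            "gbdt", grid={"n_estimators": [10], "max_depth": [2]},
            budget="exhaustive",
        )
        res = cv.replicated_cv(
            {"informative": signal, "noise": noise}, y,
            cv.CVScheme(5, 3, 1), grid,
        )
        df = cv.build_comparison_table(res, reference="informative").frame
        assert df.loc[df.method == "informative", "best"].item()
        assert not df.loc[df.method == "noise", "best"].item()


class TestEmbed2D:
    def test_tsne_shape_and_determinism(self, rng):
        X = rng.normal(size=(90, 10))
        a = cv.embed_2d(X, "tsne", seed=0)
        assert a.shape == (90, 2)
        np.testing.assert_allclose(a, cv.embed_2d(X, "tsne", seed=0))

    def test_tsne_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            cv.embed_2d(rng.normal(size=(30, 4)), "tsne")

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="method"):
            cv.embed_2d(rng.normal(size=(90, 4)), "pca2d")

    def test_tsne_preserves_separated_clusters(self, rng):
        centers = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0]])
        lbl = np.repeat([0, 1, 2], 40)
        X = centers[lbl] + rng.normal(scale=0.4, size=(120, 3))
        emb = cv.embed_2d(X, "tsne", seed=0)
        km = KMeans(3, n_init=10, random_state=0).fit_predict(emb)
        assert adjusted_rand_score(lbl, km) >= 0.8

    def test_umap_shape(self, rng):
        X = rng.normal(size=(80, 6))
        emb = cv.embed_2d(X, "umap", seed=0, n_neighbors=15)
        assert emb.shape == (80, 2)
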