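"""VAE core: reparameterization, losses, KL, objective, training, codec."""

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import chemovae as cv
from chemovae.vae import (
    VAEArchitecture,
    _objective_and_grads,
    init_params,
    vae_objective,
)


class TestReparameterize:
    def test_zero_eps_gives_mu(self):
        np.testing.assert_allclose(
            cv.reparameterize([1.0, 2.0], [4.0, 9.0], [0.0, 0.0]), [1.0, 2.0]
        )

    def test_hand_example(self):
        np.testing.assert_allclose(
            cv.reparameterize([1.0, 2.0], [4.0, 9.0], [1.0, -1.0]), [3.0, -1.0]
        )

    def test_nonpositive_var_rejected(self):
        with pytest.raises(ValueError, match="var"):
            cv.reparameterize([0.0], [0.0], [1.0])

    def test_monte_carlo_mean(self, rng):
        mu, var = np.array([0.5, -1.0]), np.array([2.0, 0.3])
        draws = cv.reparameterize(
            mu, var, rng.standard_normal((100_000, 2))
        )
        tol = 3 * np.sqrt(var / 100_000)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < tol)


class TestReconstructionLoss:
    def test_perfect_reconstruction_zero(self):
        x = np.array([0.3, 0.7])
        assert cv.reconstruction_loss(x, [x], "l1") == 0.0

    @pytest.mark.parametrize("kind,expected", [("l1", 0.6), ("l2", 0.18)])
    def test_hand_example(self, kind, expected):
        x, xr = np.array([0.2, 0.8]), np.array([0.5, 0.5])
        assert cv.reconstruction_loss(x, [xr], kind) == pytest.approx(expected)

    def test_draws_averaged(self):
        x = np.array([0.0, 0.0])
        a, b = np.array([0.5, 0.5]), np.array([1.0, 1.0])
        la = cv.reconstruction_loss(x, [a], "l1")
        lb = cv.reconstruction_loss(x, [b], "l1")
        both = cv.reconstruction_loss(x, [a, b], "l1")
        assert both == pytest.approx((la + lb) / 2)

    def test_bce_matches_closed_form(self):
        x, xr = np.array([1.0, 0.0]), np.array([0.8, 0.3])
        expected = -(np.log(0.8) + np.log(0.7))
        assert cv.reconstruction_loss(x, [xr], "bce") == pytest.approx(expected)

    def test_bce_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            cv.reconstruction_loss(np.array([0.5]), [np.array([1.5])], "bce")


class TestKL:
    def test_standard_normal_is_zero(self):
        assert cv.kl_closed_form(np.zeros(7), np.ones(7)) == 0.0

    def test_unit_mean_is_half(self):
        assert cv.kl_closed_form([1.0], [1.0]) == pytest.approx(0.5)

    def test_var_e_closed_form(self):
        assert cv.kl_closed_form([0.0], [np.e]) == pytest.approx((np.e - 2) / 2)

    def test_nonnegative_everywhere(self, rng):
        for _ in range(200):
            mu = rng.normal(size=5)
            var = rng.uniform(0.05, 5.0, size=5)
            assert cv.kl_closed_form(mu, var) >= 0.0

    def test_monte_carlo_oracle(self, rng):
        """Closed form matches E_q[log q(z) - log p(z)] by simulation."""
        mu = rng.uniform(-1, 1, size=5)
        var = rng.uniform(0.5, 2.0, size=5)
        z = mu + np.sqrt(var) * rng.standard_normal((200_000, 5))
        log_q = -0.5 * (((z - mu) ** 2) / var + np.log(2 * np.pi * var)).sum(axis=1)
        log_p = -0.5 * ((z ** 2) + np.log(2 * np.pi)).sum(axis=1)
        mc = (log_q - log_p).mean()
        assert cv.kl_closed_form(mu, var) == pytest.approx(mc, abs=0.02)

    def test_paper_literal_variant_differs(self):
        mu, var = np.array([0.3]), np.array([0.7])
        std = cv.kl_closed_form(mu, var)
        lit = cv.kl_closed_form(mu, var, paper_literal=True)
        assert std != pytest.approx(lit)


class TestObjective:
    def test_reduces_to_reconstruction_when_posterior_standard(self, rng):
        """KL contributes zero when mu=0, var=1: check additivity of terms."""
        assert cv.kl_closed_form(np.zeros(4), np.ones(4)) == 0.0

    def test_batch_additivity_fixed_eps(self, rng):
        arch = VAEArchitecture(latent_dim=3, n_layers=2)
        p = init_params(arch, 6, np.random.default_rng(0))
        X = rng.random((5, 6))
        eps = rng.standard_normal((2, 5, 3))
        whole = vae_objective(X, p, eps=eps)
        parts = sum(
            vae_objective(X[i : i + 1], p, eps=eps[:, i : i + 1, :])
            for i in range(5)
        )
        assert whole == pytest.approx(parts, rel=1e-10)

    @pytest.mark.parametrize("loss", ["l1", "l2", "bce"])
    def test_finite_difference_gradients(self, loss, rng):
        arch = VAEArchitecture(latent_dim=3, n_layers=2, loss_kind=loss)
        p = init_params(arch, 5, np.random.default_rng(1))
        X = rng.random((4, 5)) * 0.8 + 0.1
        eps = rng.standard_normal((2, 4, 3))
        _, grads = _objective_and_grads(p, X, eps)
        flat = p.flat()
        h = 1e-6
        for i in range(len(flat)):
            arr = flat[i]
            idx = (0,) if arr.ndim == 1 else (0, 0)
            old = arr[idx]
            arr[idx] = old + h
            o1, _ = _objective_and_grads(p, X, eps)
            arr[idx] = old - h
            o2, _ = _objective_and_grads(p, X, eps)
            arr[idx] = old
            fd = (o1 - o2) / (2 * h)
            assert grads[i][idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_dimension_mismatch_rejected(self, rng):
        arch = VAEArchitecture(latent_dim=2, n_layers=1)
        p = init_params(arch, 4, np.random.default_rng(0))
        with pytest.raises(ValueError, match="features"):
            vae_objective(rng.random((3, 7)), p)


class TestTraining:
    def test_objective_decreases(self, small_features):
        arch = VAEArchitecture(latent_dim=4, n_layers=2)
        p = cv.train_vae(small_features, arch, seed=0, max_epochs=40)
        assert p.training_log[-1] < p.training_log[0]
        assert p.trained

    def test_same_seed_identical_log(self, small_features):
        arch = VAEArchitecture(latent_dim=4, n_layers=2)
        a = cv.train_vae(small_features, arch, seed=5, max_epochs=10)
        b = cv.train_vae(small_features, arch, seed=5, max_epochs=10)
        assert a.training_log == b.training_log

    def test_fit_beats_init_on_heldout(self, rng):
        """Trained h=2 VAE halves held-out L1 error vs an untrained one on
        data from a 2-dim latent factor model."""
        W = rng.normal(size=(2, 60))
        z = rng.normal(size=(160, 2))
        X = 1 / (1 + np.exp(-(z @ W)))
        train, test = X[:120], X[120:]
        arch = VAEArchitecture(latent_dim=2, n_layers=2)
        fitted = cv.train_vae(train, arch, seed=0, max_epochs=400, patience=30)
        virgin = init_params(arch, 60, np.random.default_rng(0))
        virgin.trained = True

        def heldout_l1(params):
            z = cv.encode(test, params, deterministic=True).mu
            return np.abs(cv.decode(z, params) - test).sum()

        assert heldout_l1(fitted) < 0.5 * heldout_l1(virgin)

    def test_out_of_range_data_rejected(self):
        arch = VAEArchitecture(latent_dim=2, n_layers=1)
        with pytest.raises(ValueError, match="0, 1"):
            cv.train_vae(np.array([[2.0, 0.5]]), arch)


class TestEncodeDecode:
    def test_deterministic_mode_returns_mu(self, trained_vae, small_features):
        enc = cv.encode(small_features.values[0], trained_vae, deterministic=True)
        np.testing.assert_array_equal(enc.z, enc.mu)

    def test_same_seed_same_draw(self, trained_vae, small_features):
        x = small_features.values[3]
        a = cv.encode(x, trained_vae, seed=9)
        b = cv.encode(x, trained_vae, seed=9)
        np.testing.assert_array_equal(a.z, b.z)

    def test_draw_variance_matches_encoder_variance(self, trained_vae, small_features):
        x = small_features.values[0]
        enc = cv.encode(x, trained_vae, deterministic=True)
        rng = np.random.default_rng(0)
        draws = cv.reparameterize(
            enc.mu, enc.var, rng.standard_normal((10_000, len(enc.mu)))
        )
        emp = draws.var(axis=0, ddof=1)
        assert np.all(np.abs(emp - enc.var) / enc.var < 0.08)

    def test_untrained_params_rejected(self, small_features):
        arch = VAEArchitecture(latent_dim=2, n_layers=1)
        p = init_params(arch, small_features.n_features, np.random.default_rng(0))
        with pytest.raises(ValueError, match="trained"):
            cv.encode(small_features.values[0], p)

    def test_decode_range_and_determinism(self, trained_vae, rng):
        z = rng.normal(size=(100, 8))
        out = cv.decode(z, trained_vae)
        assert out.min() >= 0.0 and out.max() <= 1.0
        np.testing.assert_array_equal(out, cv.decode(z, trained_vae))

    def test_decode_dimension_mismatch(self, trained_vae):
        with pytest.raises(ValueError, match="latent"):
            cv.decode(np.zeros(5), trained_vae)

    def test_reconstruction_beats_random_latents(self, trained_vae, small_features, rng):
        X = small_features.values[:40]
        mu = cv.encode(X, trained_vae, deterministic=True).mu
        err_enc = np.abs(cv.decode(mu, trained_vae) - X).mean()
        zr = rng.normal(size=mu.shape) * 3
        err_rand = np.abs(cv.decode(zr, trained_vae) - X).mean()
        assert err_enc < err_rand


class TestScientificProperties:
    def test_l2_loss_affine_in_gaussian_loglik(self, rng):
        """Squared-error loss is an affine function of the Gaussian
        log-likelihood (unit variance) on random inputs."""
        x = rng.random(10)
        recons = [rng.random(10) for _ in range(20)]
        l2 = np.array([cv.reconstruction_loss(x, [r], "l2") for r in recons])
        loglik = np.array([
            -0.5 * ((x - r) ** 2).sum() - 5 * np.log(2 * np.pi) for r in recons
        ])
        fit = np.polyfit(loglik, l2, 1)
        np.testing.assert_allclose(np.polyval(fit, loglik), l2, atol=1e-9)
        assert fit[0] == pytest.approx(-2.0)

    def test_latent_space_preserves_cancer_types(self, trained_vae, small_features, small_cohort):
        mu = cv.encode(small_features, trained_vae, deterministic=True).mu
        km = KMeans(3, n_init=10, random_state=0).fit_predict(mu)
        assert adjusted_rand_score(small_cohort.type_of, km) >= 0.8
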