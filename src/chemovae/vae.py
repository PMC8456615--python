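"""Variational autoencoder for tumor transcriptome encoding.

The encoder maps a min-max-scaled expression vector x in [0,1]^m to the
mean and variance of a diagonal-Gaussian latent variable Z|x in R^h; a
single reparameterized draw z = mu + sqrt(var) * eps (eps ~ N(0, I)) is the
per-tumor encoding handed to the downstream classifier. The decoder maps z
back to [0,1]^m through a mirrored network with a sigmoid output. Training
minimizes, summed over tumors,

    E_eps || x - g(mu(x) + sqrt(var(x)) * eps) ||_p^p
    + D_KL( N(mu(x), diag(var(x))) || N(0, I) ),

with the reconstruction expectation approximated by averaging over J draws
and the KL in its Gaussian closed form

    0.5 * sum_i ( mu_i^2 + var_i - log var_i - 1 ).

The reconstruction norm p is configurable (L1 default, L2, or elementwise
binary cross-entropy). Optimization is Adam (learning_rate 2e-3, beta_1
0.9, beta_2 0.999) on mini-batches. The encoder net outputs log-variance,
so the variance is positive by construction.

A ``paper_literal_kl`` flag additionally exposes a non-standard printed
variant of the regularizer (||mu||_2^2 + ||var||_2^2 - ||log var||_1 - 1)
for side-by-side comparison; it is not the default because it is not the
KL divergence of the stated Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureMatrix
from .nn import Adam, Sequential, _activate_grad, geometric_widths

_LOGVAR_CLIP = 10.0
_LOSS_KINDS = ("l1", "l2", "bce")


@dataclass
class VAEArchitecture:
    """Layer plan of a VAE (decoder mirrors the encoder).

    ``n_layers`` counts fully-connected weight layers in the encoder,
    including the final latent (mu / log-var) layer. Hidden widths are
    geometrically interpolated between the input dimension m and the
    latent dimension h, fixed so architectures are reproducible.

    Named presets follow the three response-prediction architectures:
    VAE-1 (h=50, six layers, deep), VAE-2 (h=400, two layers) and VAE-3
    (h=500, two layers).
    """

    name: str = "custom"
    latent_dim: int = 50
    n_layers: int = 6
    loss_kind: str = "l1"
    mc_samples: int = 1
    kl_weight: float = 1.0
    paper_literal_kl: bool = False

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        self.loss_kind = self.loss_kind.lower()
        if self.loss_kind not in _LOSS_KINDS:
            raise ValueError(f"loss_kind must be one of {_LOSS_KINDS}")

    def widths(self, m: int) -> list[int]:
        return geometric_widths(m, self.latent_dim, self.n_layers)


def vae1(**kw) -> VAEArchitecture:
    return VAEArchitecture(name="VAE-1", latent_dim=kw.pop("latent_dim", 50),
                           n_layers=6, **kw)


def vae2(**kw) -> VAEArchitecture:
    return VAEArchitecture(name="VAE-2", latent_dim=kw.pop("latent_dim", 400),
                           n_layers=2, **kw)


def vae3(**kw) -> VAEArchitecture:
    return VAEArchitecture(name="VAE-3", latent_dim=kw.pop("latent_dim", 500),
                           n_layers=2, **kw)


ARCH_PRESETS = {"vae1": vae1, "vae2": vae2, "vae3": vae3}


@dataclass
class LatentEncoding:
    """Per-sample latent summary: posterior mean, variance and one draw."""

    mu: np.ndarray
    var: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.mu) == len(self.var) == len(self.z)):
            raise ValueError("mu, var, z must share length")
        if np.any(self.var <= 0):
            raise ValueError("var must be strictly positive")


@dataclass
class VAEParams:
    """Fitted weights: encoder trunk + mu / log-var heads (theta) and the
    mirrored decoder (phi), plus the per-epoch training objective."""

    arch: VAEArchitecture
    n_features: int
    trunk: list = field(repr=False, default=None)       # encoder hidden layers
    mu_head: tuple = field(repr=False, default=None)
    logvar_head: tuple = field(repr=False, default=None)  # absent for plain AE
    decoder: list = field(repr=False, default=None)
    training_log: list[float] = field(default_factory=list)
    trained: bool = False
    variational: bool = True

    def networks(self) -> tuple[Sequential, Sequential]:
        w = self.arch.widths(self.n_features)
        trunk_net = Sequential(w[:-1], ["relu"] * (len(w) - 2))
        dec_w = list(reversed(w))
        dec_net = Sequential(dec_w, ["relu"] * (len(dec_w) - 2) + ["sigmoid"])
        return trunk_net, dec_net

    def flat(self) -> list[np.ndarray]:
        out = []
        for W, b in self.trunk:
            out.extend([W, b])
        out.extend(self.mu_head)
        out.extend([W for p in self.decoder for W in p])
        if self.logvar_head is not None:
            out.extend(self.logvar_head)
        return out


def init_params(
    arch: VAEArchitecture, n_features: int, rng: np.random.Generator,
    variational: bool = True,
) -> VAEParams:
    """Initialize weights. Draw order is trunk, mu head, decoder, then the
    log-var head last, so a plain autoencoder (no log-var head) built from
    the same seed shares every other initial weight with the VAE."""
    w = arch.widths(n_features)
    trunk_net = Sequential(w[:-1], ["relu"] * (len(w) - 2))
    trunk = trunk_net.init_params(rng)
    head_net = Sequential(w[-2:], ["linear"])
    mu_head = head_net.init_params(rng)[0]
    dec_w = list(reversed(w))
    dec_net = Sequential(dec_w, ["relu"] * (len(dec_w) - 2) + ["sigmoid"])
    decoder = dec_net.init_params(rng)
    if variational:
        Wl, bl = head_net.init_params(rng)[0]
        # start nearly deterministic (var ~ e^-4): the decoder then learns to
        # use the latent code before sampling noise is turned up, which
        # guards against posterior collapse
        logvar_head = (Wl, bl - 4.0)
    else:
        logvar_head = None
    return VAEParams(
        arch=arch, n_features=n_features, trunk=trunk, mu_head=mu_head,
        logvar_head=logvar_head, decoder=decoder, variational=variational,
    )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def reparameterize(mu: np.ndarray, var: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = mu + sqrt(var) * eps, elementwise."""
    mu, var, eps = (np.asarray(a, dtype=float) for a in (mu, var, eps))
    if np.any(var <= 0):
        raise ValueError("var must be strictly positive")
    return mu + np.sqrt(var) * eps


def reconstruction_loss(x, x_recon_per_draw, kind: str = "l1") -> float:
    """Average over draws of ||x - x_tilde||_p^p (or summed elementwise
    binary cross-entropy)."""
    kind = kind.lower()
    if kind not in _LOSS_KINDS:
        raise ValueError(f"kind must be one of {_LOSS_KINDS}")
    x = np.asarray(x, dtype=float)
    draws = [np.asarray(d, dtype=float) for d in x_recon_per_draw]
    if not draws:
        raise ValueError("need at least one reconstruction draw")
    total = 0.0
    for d in draws:
        if d.shape != x.shape:
            raise ValueError("reconstruction shape mismatch")
        if kind == "l1":
            total += float(np.abs(x - d).sum())
        elif kind == "l2":
            total += float(((x - d) ** 2).sum())
        else:
            if d.min() < -1e-6 or d.max() > 1.0 + 1e-6:
                raise ValueError("BCE reconstruction outside [0, 1]")
            dc = np.clip(d, 1e-7, 1.0 - 1e-7)
            total += float(-(x * np.log(dc) + (1.0 - x) * np.log(1.0 - dc)).sum())
    return total / len(draws)


def kl_closed_form(mu: np.ndarray, var: np.ndarray, paper_literal: bool = False) -> float:
    """KL( N(mu, diag(var)) || N(0, I) ) in closed form.

    The default is the standard 0.5 * sum(mu^2 + var - log var - 1), which
    is nonnegative and zero exactly at mu=0, var=1. ``paper_literal``
    computes the alternative printed variant instead (see module docstring).
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(var <= 0):
        raise ValueError("var must be strictly positive")
    if paper_literal:
        return float((mu ** 2).sum() + (var ** 2).sum()
                     - np.abs(np.log(var)).sum() - 1.0)
    return float(0.5 * (mu ** 2 + var - np.log(var) - 1.0).sum())


# ---------------------------------------------------------------------------
# joint objective with gradients
# ---------------------------------------------------------------------------

def _as_values(data) -> np.ndarray:
    if isinstance(data, FeatureMatrix):
        return data.values
    return np.asarray(data, dtype=float)


def _objective_and_grads(params: VAEParams, X: np.ndarray,
                         eps: np.ndarray | None,
                         kl_weight: float | None = None):
    """Total objective over the batch and its gradient w.r.t. every weight.

    ``eps`` has shape (J, batch, h); None means deterministic (z = mu).
    ``kl_weight`` overrides the architecture's weight (used for warm-up
    annealing during training). Returns (objective, grads) with grads
    ordered as ``params.flat()``.
    """
    arch = params.arch
    trunk_net, dec_net = params.networks()
    B, m = X.shape
    if m != params.n_features:
        raise ValueError(f"expected {params.n_features} features, got {m}")
    h_dim = arch.latent_dim

    H, trunk_cache = trunk_net.forward(params.trunk, X)
    Wm, bm = params.mu_head
    mu = H @ Wm + bm
    if params.variational:
        Wl, bl = params.logvar_head
        logvar_raw = H @ Wl + bl
        logvar = np.clip(logvar_raw, -_LOGVAR_CLIP, _LOGVAR_CLIP)
        clip_mask = (np.abs(logvar_raw) < _LOGVAR_CLIP).astype(float)
        var = np.exp(logvar)
    else:
        logvar = var = None

    if eps is None:
        eps = np.zeros((1, B, h_dim))
    J = eps.shape[0]

    recon_total = 0.0
    dec_grads = None
    d_mu = np.zeros_like(mu)
    d_logvar = np.zeros_like(mu)
    sqrt_var = np.sqrt(var) if var is not None else None
    for j in range(J):
        z = mu + sqrt_var * eps[j] if params.variational else mu + eps[j] * 0.0
        xhat, dec_cache = dec_net.forward(params.decoder, z)
        kind = arch.loss_kind
        if kind == "l1":
            recon_total += np.abs(X - xhat).sum() / J
            d_xhat = np.sign(xhat - X)
            d_a = d_xhat * xhat * (1.0 - xhat)
        elif kind == "l2":
            recon_total += ((X - xhat) ** 2).sum() / J
            d_xhat = 2.0 * (xhat - X)
            d_a = d_xhat * xhat * (1.0 - xhat)
        else:  # bce; with a sigmoid output the pre-activation grad is xhat - x
            xc = np.clip(xhat, 1e-7, 1.0 - 1e-7)
            recon_total += -(X * np.log(xc) + (1.0 - X) * np.log(1.0 - xc)).sum() / J
            d_a = xhat - X
        # feed the pre-activation gradient directly into the final layer:
        # replace the sigmoid-grad chain by patching d_out for layer -1
        g, dz = _decoder_backward(dec_net, params.decoder, dec_cache, d_a)
        if dec_grads is None:
            dec_grads = [(gw / J, gb / J) for gw, gb in g]
        else:
            dec_grads = [(aw + gw / J, ab + gb / J)
                         for (aw, ab), (gw, gb) in zip(dec_grads, g)]
        d_mu += dz / J
        if params.variational:
            d_logvar += dz * eps[j] * 0.5 * sqrt_var / J

    objective = recon_total
    w = arch.kl_weight if kl_weight is None else kl_weight
    if params.variational and w != 0.0:
        if arch.paper_literal_kl:
            kl = ((mu ** 2).sum() + (var ** 2).sum()
                  - np.abs(logvar).sum() - B * 1.0)
            d_mu += w * 2.0 * mu
            d_logvar += w * (2.0 * var ** 2 - np.sign(logvar))
        else:
            kl = 0.5 * (mu ** 2 + var - logvar - 1.0).sum()
            d_mu += w * mu
            d_logvar += w * 0.5 * (var - 1.0)
        objective += w * kl

    # back through the heads and the trunk
    Wm, _ = params.mu_head
    mu_grads = (H.T @ d_mu, d_mu.sum(axis=0))
    dH = d_mu @ Wm.T
    if params.variational:
        d_lv_raw = d_logvar * clip_mask
        Wl, _ = params.logvar_head
        lv_grads = (H.T @ d_lv_raw, d_lv_raw.sum(axis=0))
        dH = dH + d_lv_raw @ Wl.T
    trunk_grads, _ = trunk_net.backward(params.trunk, trunk_cache, dH)

    flat = []
    for gw, gb in trunk_grads:
        flat.extend([gw, gb])
    flat.extend(mu_grads)
    for gw, gb in dec_grads:
        flat.extend([gw, gb])
    if params.variational:
        flat.extend(lv_grads)
    return float(objective), flat


def _decoder_backward(net: Sequential, p, cache, d_pre_final):
    """Backprop where the gradient is given w.r.t. the final pre-activation
    (skips the final activation derivative)."""
    grads = [None] * len(p)
    h, a, out = cache[-1]
    da = d_pre_final
    grads[-1] = (h.T @ da, da.sum(axis=0))
    g = da @ p[-1][0].T
    for i in range(len(p) - 2, -1, -1):
        W, _ = p[i]
        h, a, out = cache[i]
        da = g * _activate_grad(a, out, net.activations[i])
        grads[i] = (h.T @ da, da.sum(axis=0))
        g = da @ W.T
    return grads, g


def vae_objective(batch, params: VAEParams, eps: np.ndarray | None = None,
                  seed: int | None = None) -> float:
    """Sum over the batch of reconstruction loss + KL regularizer.

    With ``eps=None`` and a seed, mc_samples standard-normal draws are
    used; with ``eps=None`` and no seed the evaluation is deterministic
    (z = mu)."""
    X = _as_values(batch)
    if X.ndim == 1:
        X = X[None, :]
    if eps is None and seed is not None:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal(
            (params.arch.mc_samples, X.shape[0], params.arch.latent_dim)
        )
    obj, _ = _objective_and_grads(params, X, eps)
    return obj


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _check_unit_interval(X: np.ndarray) -> None:
    if X.min(initial=0.0) < -1e-9 or X.max(initial=0.0) > 1.0 + 1e-9:
        raise ValueError("training data must lie in [0, 1] (min-max scale it)")


def train_vae(
    data,
    arch: VAEArchitecture,
    seed: int = 0,
    max_epochs: int = 200,
    batch_size: int = 64,
    patience: int = 10,
    learning_rate: float = 2e-3,
    beta_1: float = 0.9,
    beta_2: float = 0.999,
    variational: bool = True,
    kl_anneal_epochs: int = 50,
    deterministic_z: bool = False,
    callback=None,
) -> VAEParams:
    """Fit by mini-batch Adam; deterministic given the seed.

    The KL weight is linearly warmed up from 0 to its target over the first
    ``kl_anneal_epochs`` epochs (a standard guard against posterior
    collapse; the converged objective is unchanged). Stops early when the
    per-sample training objective has not improved by a relative 1e-4 for
    ``patience`` epochs, counted only once the warm-up is over. The
    per-epoch mean of the actually-minimized objective is recorded in
    ``training_log``.
    """
    X = _as_values(data)
    _check_unit_interval(X)
    n, m = X.shape
    # independent streams so the data-order stream is unaffected by how many
    # draws initialization consumes (lets matched AE/VAE runs share batches)
    init_rng, rng = (np.random.default_rng(s)
                     for s in np.random.SeedSequence(seed).spawn(2))
    params = init_params(arch, m, init_rng, variational=variational)
    opt = Adam(lr=learning_rate, beta_1=beta_1, beta_2=beta_2)
    best = np.inf
    since_best = 0
    for epoch in range(max_epochs):
        if variational and kl_anneal_epochs > 0:
            kl_w = arch.kl_weight * min(1.0, (epoch + 1) / kl_anneal_epochs)
        else:
            kl_w = arch.kl_weight
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = X[idx]
            if variational and not deterministic_z:
                eps = rng.standard_normal(
                    (arch.mc_samples, len(idx), arch.latent_dim)
                )
            else:
                eps = None
            obj, grads = _objective_and_grads(params, xb, eps, kl_weight=kl_w)
            if not np.isfinite(obj):
                raise RuntimeError(
                    f"non-finite objective at epoch {epoch}, "
                    f"batch starting at {start}"
                )
            total += obj
            scale = 1.0 / len(idx)
            opt.step(params.flat(), [g * scale for g in grads])
        per_sample = total / n
        params.training_log.append(per_sample)
        if callback is not None:
            callback(epoch, per_sample)
        if variational and epoch + 1 < kl_anneal_epochs:
            continue  # objective scale still changing during warm-up
        if per_sample < best * (1.0 - 1e-4):
            best = per_sample
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    params.trained = True
    return params


# ---------------------------------------------------------------------------
# encoding / decoding
# ---------------------------------------------------------------------------

def _encode_arrays(X: np.ndarray, params: VAEParams):
    trunk_net, _ = params.networks()
    H, _ = trunk_net.forward(params.trunk, X)
    Wm, bm = params.mu_head
    mu = H @ Wm + bm
    if params.variational:
        Wl, bl = params.logvar_head
        var = np.exp(np.clip(H @ Wl + bl, -_LOGVAR_CLIP, _LOGVAR_CLIP))
    else:
        var = np.ones_like(mu)
    return mu, var


def encode(x, params: VAEParams, seed: int | None = None,
           deterministic: bool = False) -> LatentEncoding:
    """Encode one sample; z is a single reparameterized draw (or z = mu in
    deterministic mode)."""
    if not params.trained:
        raise ValueError("params are not trained")
    x = np.asarray(_as_values(x), dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    mu, var = _encode_arrays(X, params)
    if deterministic or not params.variational:
        z = mu.copy()
    else:
        rng = np.random.default_rng(seed)
        z = reparameterize(mu, var, rng.standard_normal(mu.shape))
    if single:
        return LatentEncoding(mu[0], var[0], z[0])
    return LatentEncoding(mu, var, z)


def encode_matrix(data, params: VAEParams, seed: int | None = None,
                  deterministic: bool = False) -> FeatureMatrix:
    """Encode a whole FeatureMatrix into latent space (state='latent')."""
    enc = encode(data, params, seed=seed, deterministic=deterministic)
    ids = [f"z{i}" for i in range(params.arch.latent_dim)]
    sample_ids = (data.sample_ids if isinstance(data, FeatureMatrix)
                  else [str(i) for i in range(enc.z.shape[0])])
    return FeatureMatrix(enc.z, sample_ids, ids, "latent")


def decode(z, params: VAEParams) -> np.ndarray:
    """Map latent vectors back to [0,1]^m (sigmoid output)."""
    if not params.trained:
        raise ValueError("params are not trained")
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    Z = z[None, :] if single else z
    if Z.shape[1] != params.arch.latent_dim:
        raise ValueError(
            f"expected latent dim {params.arch.latent_dim}, got {Z.shape[1]}"
        )
    _, dec_net = params.networks()
    out, _ = dec_net.forward(params.decoder, Z)
    return out[0] if single else out
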