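"""Minimal dense-network machinery (forward, backprop, Adam).

Small fully-connected nets with explicit parameter lists, sized for
desk-scale transcriptome encoders. Kept deliberately simple: ReLU hidden
units, sigmoid or linear outputs, He/Glorot initialization, and an Adam
optimizer with the conventional moment estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_ACTS = ("relu", "sigmoid", "linear")


def _activate(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(a, 0.0)
    if kind == "sigmoid":
        # clipped for overflow safety; outputs stay in (0, 1)
        return 1.0 / (1.0 + np.exp(-np.clip(a, -60.0, 60.0)))
    return a


def _activate_grad(a: np.ndarray, out: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (a > 0.0).astype(a.dtype)
    if kind == "sigmoid":
        return out * (1.0 - out)
    return np.ones_like(a)


@dataclass
class Sequential:
    """A chain of dense layers; params live outside as [(W, b), ...]."""

    widths: list[int]          # [in, w1, ..., out]
    activations: list[str]     # one per weight layer

    def __post_init__(self) -> None:
        if len(self.activations) != len(self.widths) - 1:
            raise ValueError("need one activation per weight layer")
        for a in self.activations:
            if a not in _ACTS:
                raise ValueError(f"unknown activation {a!r}")

    def init_params(self, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
        params = []
        for d_in, d_out, act in zip(self.widths, self.widths[1:], self.activations):
            if act == "relu":
                scale = np.sqrt(2.0 / d_in)
            else:
                scale = np.sqrt(1.0 / d_in)
            W = rng.normal(0.0, scale, size=(d_in, d_out))
            b = np.zeros(d_out)
            params.append((W, b))
        return params

    def forward(self, params, X):
        """Returns (output, cache) where cache holds per-layer inputs,
        pre-activations and outputs for backprop."""
        cache = []
        h = X
        for (W, b), act in zip(params, self.activations):
            a = h @ W + b
            out = _activate(a, act)
            cache.append((h, a, out))
            h = out
        return h, cache

    def backward(self, params, cache, d_out):
        """Backprop a gradient w.r.t. the network output.

        Returns (param_grads, d_input)."""
        grads = [None] * len(params)
        g = d_out
        for i in range(len(params) - 1, -1, -1):
            W, _ = params[i]
            h, a, out = cache[i]
            da = g * _activate_grad(a, out, self.activations[i])
            grads[i] = (h.T @ da, da.sum(axis=0))
            g = da @ W.T
        return grads, g


class Adam:
    """Adam over a flat list of arrays (updates in place)."""

    def __init__(self, lr=2e-3, beta_1=0.9, beta_2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta_1, beta_2, eps
        self.t = 0
        self._m = None
        self._v = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.b1, self.b2
        lr_t = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def geometric_widths(m: int, h: int, n_layers: int) -> list[int]:
    """Layer widths from m down to h over ``n_layers`` weight layers,
    geometrically interpolated (so successive compression ratios match)."""
    if n_layers < 1:
        raise ValueError("need at least one layer")
    ts = np.arange(1, n_layers) / n_layers
    hidden = [int(round(np.exp((1 - t) * np.log(m) + t * np.log(h)))) for t in ts]
    hidden = [max(w, max(h, 1)) for w in hidden]
    return [m, *hidden, h]
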