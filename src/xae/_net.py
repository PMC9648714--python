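"""Minimal dense autoencoder network with manual backprop and Adam.

Architecture (all strategies): flatten -> dense(d, tanh) -> latent head ->
dense(d, tanh) -> dense(p, sigmoid) -> reshape. The latent head is linear and
emits ``d_latent`` values for AE/DAE or ``2 * d_latent`` (means and
log-variances) for the VAE. Losses are binary cross entropy summed over
cells and averaged over the batch; the VAE adds the analytic KL of the
diagonal-Gaussian posterior from N(0, I).
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7  # cross-entropy clipping


def bce_sum(target: np.ndarray, output: np.ndarray) -> float:
    """Binary cross entropy summed over all cells (outputs clipped to [eps, 1-eps])."""
    o = np.clip(output, EPS, 1.0 - EPS)
    return float(-(target * np.log(o) + (1.0 - target) * np.log(1.0 - o)).sum())


def kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(mu, diag exp(logvar)) || N(0, I) ), summed over dimensions."""
    return float(0.5 * (mu ** 2 + np.exp(logvar) - logvar - 1.0).sum())


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class DenseAutoencoderNet:
    """Weight container + forward/backward passes. Not user-facing."""

    def __init__(self, p: int, hidden: int, latent: int, variational: bool,
                 rng: np.random.Generator, output_bias_init: float = 0.0):
        head = 2 * latent if variational else latent
        self.p, self.hidden, self.latent = p, hidden, latent
        self.variational = variational
        self.params = {
            "W1": _glorot(rng, p, hidden), "b1": np.zeros(hidden),
            "W2": _glorot(rng, hidden, head), "b2": np.zeros(head),
            "W3": _glorot(rng, latent, hidden), "b3": np.zeros(hidden),
            "W4": _glorot(rng, hidden, p), "b4": np.full(p, output_bias_init),
        }

    # -- inference ---------------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        """Latent head output; (B, d_latent) or (B, 2*d_latent) for VAE."""
        P = self.params
        h1 = np.tanh(x @ P["W1"] + P["b1"])
        return h1 @ P["W2"] + P["b2"]

    def decode(self, z: np.ndarray) -> np.ndarray:
        P = self.params
        h2 = np.tanh(z @ P["W3"] + P["b3"])
        return _sigmoid(h2 @ P["W4"] + P["b4"])

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Deterministic decode: the VAE uses the posterior mean."""
        lat = self.encode(x)
        z = lat[:, : self.latent] if self.variational else lat
        return self.decode(z)

    # -- training ----------------------------------------------------------
    def loss_and_grads(
        self, x: np.ndarray, target: np.ndarray, rng: np.random.Generator | None
    ) -> tuple[float, float, dict[str, np.ndarray]]:
        """Mean-over-batch loss (rec, kl) and parameter gradients.

        ``rng`` draws the VAE reparameterisation sample; pass None for AE/DAE.
        """
        P = self.params
        B = x.shape[0]
        h1 = np.tanh(x @ P["W1"] + P["b1"])
        lat = h1 @ P["W2"] + P["b2"]
        if self.variational:
            mu, logvar = lat[:, : self.latent], lat[:, self.latent:]
            eps = rng.standard_normal(mu.shape)
            sigma = np.exp(0.5 * logvar)
            z = mu + sigma * eps
            kl = 0.5 * (mu ** 2 + np.exp(logvar) - logvar - 1.0).sum() / B
        else:
            z, kl = lat, 0.0
        h2 = np.tanh(z @ P["W3"] + P["b3"])
        out = _sigmoid(h2 @ P["W4"] + P["b4"])
        rec = bce_sum(target, out) / B

        d_logits = (out - target) / B          # exact BCE+sigmoid gradient
        g = {"W4": h2.T @ d_logits, "b4": d_logits.sum(0)}
        d_h2 = d_logits @ P["W4"].T
        d_pre3 = d_h2 * (1.0 - h2 ** 2)
        g["W3"] = z.T @ d_pre3
        g["b3"] = d_pre3.sum(0)
        d_z = d_pre3 @ P["W3"].T
        if self.variational:
            d_mu = d_z + mu / B
            d_logvar = d_z * eps * 0.5 * sigma + 0.5 * (np.exp(logvar) - 1.0) / B
            d_lat = np.concatenate([d_mu, d_logvar], axis=1)
        else:
            d_lat = d_z
        g["W2"] = h1.T @ d_lat
        g["b2"] = d_lat.sum(0)
        d_h1 = d_lat @ P["W2"].T
        d_pre1 = d_h1 * (1.0 - h1 ** 2)
        g["W1"] = x.T @ d_pre1
        g["b1"] = d_pre1.sum(0)
        return rec, float(kl), g

    def eval_loss(self, x: np.ndarray, target: np.ndarray) -> float:
        """Deterministic objective (posterior mean for the VAE) + KL, per element."""
        B = x.shape[0]
        lat = self.encode(x)
        if self.variational:
            mu, logvar = lat[:, : self.latent], lat[:, self.latent:]
            kl = 0.5 * (mu ** 2 + np.exp(logvar) - logvar - 1.0).sum() / B
            z = mu
        else:
            z, kl = lat, 0.0
        return bce_sum(target, self.decode(z)) / B + float(kl)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.params = {k: np.asarray(v, dtype=float).copy() for k, v in weights.items()}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, gk in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * gk
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * gk ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
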