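"""Filter/inverse autoencoder objectives and the trainable estimator.

Two training strategies turn an autoencoder into a binary classifier. Both
reconstruct positive-class matrices unchanged; they differ in the target for
negatives: the *filter* strategy (alpha = "F") maps negatives to all-zero
grids, so decoded mass measures positivity, while the *inverse* strategy
(alpha = "I") maps negatives to their complement ``1 - x``, so a low
reconstruction error flags positives. Three architectures share one dense
topology: plain AE, denoising AE (input bit-flip corruption), and VAE
(diagonal-Gaussian latent, trained by the negative ELBO with the likelihood
term replaced by the strategy objective).
"""

from __future__ import annotations

import io
import json
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._net import Adam, DenseAutoencoderNet, bce_sum, kl_gaussian
from .errors import TrainingError, ValidationError
from .predict import gini_threshold, score_filter, score_inverse

__all__ = [
    "delta_filter", "delta_inverse", "reconstruction_loss", "objective",
    "vae_objective", "corrupt", "PathwayAutoencoder",
    "save_checkpoint", "load_checkpoint",
]


def _check_class(c: int) -> int:
    if c not in (0, 1):
        raise ValueError(f"class must be 0 or 1, got {c!r}")
    return int(c)


def delta_filter(x: np.ndarray, c: int) -> np.ndarray:
    """Filter target: zeros for the negative class, the input for the positive."""
    return x if _check_class(c) == 1 else np.zeros_like(x)


def delta_inverse(x: np.ndarray, c: int) -> np.ndarray:
    """Inverse target: the complement ``1 - x`` for negatives, ``x`` for positives."""
    return x if _check_class(c) == 1 else 1.0 - x


_DELTAS = {"F": delta_filter, "I": delta_inverse}


def reconstruction_loss(target: np.ndarray, output: np.ndarray) -> float:
    """Element-wise binary cross entropy summed over all cells."""
    target = np.asarray(target, dtype=float)
    output = np.asarray(output, dtype=float)
    if target.shape != output.shape:
        raise ValueError(f"shape mismatch: {target.shape} vs {output.shape}")
    return bce_sum(target, output)


def objective(
    batch: Sequence[np.ndarray], classes: Sequence[int], outputs: Sequence[np.ndarray],
    alpha: str,
) -> float:
    """Strategy objective J^alpha: sum over the batch of BCE(delta_alpha(x), x')."""
    delta = _DELTAS[alpha]
    return sum(
        reconstruction_loss(delta(np.asarray(x, float), c), xp)
        for x, c, xp in zip(batch, classes, outputs)
    )


def vae_objective(
    batch: Sequence[np.ndarray], classes: Sequence[int], outputs: Sequence[np.ndarray],
    mus: np.ndarray, logvars: np.ndarray, alpha: str,
) -> float:
    """Negative ELBO with the likelihood term replaced by J^alpha.

    ``outputs`` are decodings of one reparameterised latent sample per
    element; the analytic KL of each diagonal-Gaussian posterior from N(0, I)
    is added. Minimised during training.
    """
    kl = kl_gaussian(np.asarray(mus, float), np.asarray(logvars, float))
    if not np.isfinite(kl):
        raise TrainingError("non-finite KL divergence")
    return objective(batch, classes, outputs, alpha) + kl


def corrupt(x: np.ndarray, noise_ratio: float, seed: int | np.random.Generator) -> np.ndarray:
    """Flip ``round(noise_ratio * p)`` distinct uniformly chosen cells to ``1 - x``.

    The input is untouched; deterministic for a fixed seed.
    """
    if not 0 <= noise_ratio < 1:
        raise ValueError("noise_ratio must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = np.array(x, dtype=float, copy=True)
    k = round(noise_ratio * out.size)
    if k:
        flat = rng.choice(out.size, size=k, replace=False)
        idx = np.unravel_index(flat, out.shape)
        out[idx] = 1.0 - out[idx]
    return out


class PathwayAutoencoder(BaseEstimator):
    """Autoencoder-based binary classifier over pathway matrices.

    Parameters
    ----------
    alpha : {"F", "I"}
        Training strategy: filter (negatives -> zeros, score = decoded mass)
        or inverse (negatives -> complement, score = inverse reconstruction
        error, in [0, 1]).
    architecture : {"AE", "DAE", "VAE"}
        Plain, denoising (bit-flip input corruption, resampled every epoch),
        or variational (diagonal Gaussian posterior; inference uses the
        posterior mean, so predictions and explanations are deterministic).
    noise_ratio : float
        Fraction of cells flipped per matrix for the DAE (0.001 = 0.1%).
    latent_dim, hidden_dim : int
        Bottleneck width d_latent and dense-layer width d. The VAE latent
        head emits ``2 * latent_dim`` values (means and log-variances).
    learning_rate, max_epochs, patience, batch_size :
        Adam step size, epoch cap, early-stopping patience on the validation
        objective, and minibatch size.
    validation_fraction : float
        Held-out share of the training set monitored for early stopping.
    random_state : int or None
        Seeds weight init, shuffling, corruption and VAE sampling.

    Attributes
    ----------
    net_ : trained network (best validation weights restored).
    history_ : list of (train_loss, val_loss) per epoch.
    threshold_ : Gini-impurity-minimising score threshold fitted on training scores.
    classes_ : array([0, 1]).
    input_shape_ : (l, w) of the fitted matrices.
    """

    def __init__(self, alpha: str = "I", architecture: str = "VAE",
                 noise_ratio: float = 0.001, latent_dim: int = 8,
                 hidden_dim: int = 32, learning_rate: float = 1e-4,
                 max_epochs: int = 5000, patience: int = 25,
                 batch_size: int = 64, validation_fraction: float = 0.1,
                 random_state: int | None = None):
        self.alpha = alpha
        self.architecture = architecture
        self.noise_ratio = noise_ratio
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_params(self) -> None:
        if self.alpha not in ("F", "I"):
            raise ValueError("alpha must be 'F' or 'I'")
        if self.architecture not in ("AE", "DAE", "VAE"):
            raise ValueError("architecture must be 'AE', 'DAE' or 'VAE'")
        if not 0 <= self.noise_ratio < 1:
            raise ValueError("noise_ratio must be in [0, 1)")
        if self.latent_dim < 1 or self.hidden_dim < self.latent_dim:
            raise ValueError("need hidden_dim >= latent_dim >= 1")

    @staticmethod
    def _as_2d(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            return X.reshape(X.shape[0], -1)
        if X.ndim == 2:
            return X
        raise ValueError("X must be (n, l, w) or (n, p)")

    def _targets(self, X2: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.alpha == "F":
            return np.where(y[:, None] == 1, X2, 0.0)
        return np.where(y[:, None] == 1, X2, 1.0 - X2)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PathwayAutoencoder":
        self._validate_params()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.any(X < 0) or np.any(X > 1):
            raise ValidationError("matrix entries must lie in [0, 1]")
        self.input_shape_ = X.shape[1:] if X.ndim == 3 else (X.shape[1],)
        X2 = self._as_2d(X)
        if len(np.unique(y)) < 2:
            raise ValidationError("training data must contain both classes")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X2.shape[1]
        rng = np.random.default_rng(self.random_state)

        # stratified validation split for early stopping
        n = X2.shape[0]
        n_val = max(2, int(round(self.validation_fraction * n)))
        order = rng.permutation(n)
        pos = order[y[order] == 1]
        neg = order[y[order] == 0]
        n_val_pos = max(1, int(round(n_val * len(pos) / n)))
        n_val_neg = max(1, n_val - n_val_pos)
        val_idx = np.concatenate([pos[:n_val_pos], neg[:n_val_neg]])
        train_idx = np.concatenate([pos[n_val_pos:], neg[n_val_neg:]])
        Xt, yt = X2[train_idx], y[train_idx]
        Xv, yv = X2[val_idx], y[val_idx]
        Tt, Tv = self._targets(Xt, yt), self._targets(Xv, yv)

        variational = self.architecture == "VAE"
        # initialise the output bias at the base-rate logit for fast convergence
        base = float(np.clip(Tt.mean(), 1e-4, 1 - 1e-4))
        bias0 = float(np.log(base / (1.0 - base)))
        net = DenseAutoencoderNet(
            X2.shape[1], self.hidden_dim, self.latent_dim, variational, rng, bias0
        )
        opt = Adam(net.params, self.learning_rate)

        best_val = np.inf
        best_weights = net.get_weights()
        best_epoch = 0
        wait = 0
        self.history_ = []
        for epoch in range(1, self.max_epochs + 1):
            if self.architecture == "DAE" and self.noise_ratio > 0:
                epoch_rng = np.random.default_rng(
                    ((self.random_state or 0) * 100003 + epoch) % (2 ** 31)
                )
                Xin = corrupt(Xt, self.noise_ratio, epoch_rng)
            else:
                Xin = Xt
            perm = rng.permutation(len(Xt))
            losses = []
            for start in range(0, len(Xt), self.batch_size):
                sel = perm[start:start + self.batch_size]
                rec, kl, grads = net.loss_and_grads(
                    Xin[sel], Tt[sel], rng if variational else None
                )
                loss = rec + kl
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch}, batch {start // self.batch_size}"
                    )
                losses.append(loss)
                opt.step(net.params, grads)
            val_loss = net.eval_loss(Xv, Tv)
            self.history_.append((float(np.mean(losses)), float(val_loss)))
            if val_loss < best_val - 1e-9:
                best_val, best_weights, best_epoch, wait = (
                    val_loss, net.get_weights(), epoch, 0
                )
            else:
                wait += 1
                if wait >= self.patience:
                    break
        net.set_weights(best_weights)
        self.net_ = net
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_val)
        try:
            self.threshold_ = gini_threshold(self.decision_function(X), y)
        except ValueError:
            self.threshold_ = float(np.mean(self.decision_function(X)))
        return self

    # ------------------------------------------------------------------
    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Decoded matrices x' = g(f(x)) with the input's shape, entries in (0,1)."""
        X = np.asarray(X, dtype=float)
        out = self.net_.reconstruct(self._as_2d(X))
        return out.reshape(X.shape)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Per-element strategy score: y^F (decoded mass) or y^I (inverse error)."""
        X = np.asarray(X, dtype=float)
        X2 = self._as_2d(X)
        out = self.net_.reconstruct(X2)
        if self.alpha == "F":
            return np.array([score_filter(o) for o in out])
        return np.array([score_inverse(x, o) for x, o in zip(X2, out)])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= self.threshold_).astype(int)


# ----------------------------------------------------------------------
def save_checkpoint(path, model: PathwayAutoencoder,
                    row_labels: list[str] | None = None,
                    rescale_factor: float | None = None) -> None:
    """Persist weights + config (+ label order and rescale factor) to one .npz."""
    meta = {
        "params": model.get_params(),
        "input_shape": list(model.input_shape_),
        "threshold": model.threshold_,
        "best_epoch": model.best_epoch_,
        "row_labels": row_labels,
        "rescale_factor": rescale_factor,
    }
    arrays = {f"weight_{k}": v for k, v in model.net_.get_weights().items()}
    buf = io.BytesIO()
    np.savez(buf, meta=json.dumps(meta), **arrays)
    with open(path, "wb") as f:
        f.write(buf.getvalue())


def load_checkpoint(path) -> tuple[PathwayAutoencoder, dict]:
    """Load a checkpoint; returns (model, metadata). Verifies shape coherence."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        weights = {k[len("weight_"):]: data[k] for k in data.files if k.startswith("weight_")}
    model = PathwayAutoencoder(**meta["params"])
    model._validate_params()
    p = int(np.prod(meta["input_shape"]))
    if weights["W1"].shape[0] != p:
        raise ValidationError(
            f"checkpoint input size {weights['W1'].shape[0]} != expected {p}"
        )
    rng = np.random.default_rng(0)
    net = DenseAutoencoderNet(
        p, model.hidden_dim, model.latent_dim, model.architecture == "VAE", rng
    )
    net.set_weights(weights)
    model.net_ = net
    model.input_shape_ = tuple(meta["input_shape"])
    model.threshold_ = meta["threshold"]
    model.best_epoch_ = meta["best_epoch"]
    model.classes_ = np.array([0, 1])
    model.n_features_in_ = p
    model.history_ = []
    return model, meta
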