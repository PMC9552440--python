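"""Bottleneck autoencoder trained with SGD on a logistic reconstruction loss.

The model is a symmetric multilayer perceptron (default 500-100-500 hidden
units) that reconstructs its input through a narrow bottleneck; the
bottleneck activations are the learned multi-omics features.  Hidden layers
use tanh; the output layer uses a sigmoid so the cross-entropy ("logloss")
reconstruction objective is defined, which is why inputs must first be
squashed into the unit interval (see :mod:`aesurv.preprocess`).

The training objective per batch is

    mean_b [ -sum_j ( x_j log x'_j + (1-x_j) log(1-x'_j) )
             + a_a * sum_i ||A_i(x_b)||_2^2 ]  +  a_w * sum_i ||W_i||_1

where ``A_i`` is the activation of layer ``i`` and the L1 weight penalty
``a_w`` and L2 activity penalty ``a_a`` control overfitting.  Gradients are
computed by hand-written backpropagation (verified against finite
differences in the test-suite) and optimized with plain stochastic
gradient descent; dropout is applied to hidden activations during training
only, so inference is deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ContractError, DivergenceError

_ACTIVATIONS = {
    "tanh": np.tanh,
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "linear": lambda z: z,
}


def layer_forward(x, W, b, activation: str = "tanh"):
    """One dense layer: ``activation(W @ x + b)`` for a single vector."""
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if W.ndim != 2 or x.shape[-1] != W.shape[1] or b.shape[0] != W.shape[0]:
        raise ContractError(
            f"shape mismatch: W {W.shape}, x {x.shape}, b {b.shape}"
        )
    if activation not in _ACTIVATIONS:
        raise ContractError(f"unknown activation {activation!r}")
    return _ACTIVATIONS[activation](x @ W.T + b)


def reconstruction_logloss(x, x_prime) -> float:
    """Summed binary cross-entropy between a target in [0,1] and a
    reconstruction in (0,1); non-negative, minimized when they agree."""
    x = np.asarray(x, dtype=float)
    xp = np.asarray(x_prime, dtype=float)
    if x.shape != xp.shape:
        raise ContractError("x and x_prime must have the same shape")
    if np.any((x < 0) | (x > 1)):
        raise ContractError("x components must lie in [0, 1]")
    if np.any((xp <= 0) | (xp >= 1)):
        raise ContractError("x_prime components must lie strictly in (0, 1)")
    return float(-np.sum(x * np.log(xp) + (1 - x) * np.log(1 - xp)))


class Autoencoder(TransformerMixin, BaseEstimator):
    """Symmetric tanh autoencoder with a logistic output layer.

    Parameters
    ----------
    hidden_sizes : odd-length tuple of int, default (500, 100, 500)
        Hidden layer widths; the middle entry is the bottleneck.
    l1_weight, l2_activity : float
        The L1 weight and L2 activity regularization strengths.
    learning_rate, epochs, batch_size, dropout :
        Plain-SGD training hyperparameters.  The defaults reproduce the
        reference settings (lr 1e-6, 10 epochs, batch 32, 50% dropout);
        note lr 1e-6 over 10 epochs barely moves the weights — use a
        larger rate when latent quality matters.
    random_state : int
        Seeds initialization, batch shuffling and dropout; a fixed seed
        makes training bit-reproducible.
    """

    def __init__(
        self,
        hidden_sizes=(500, 100, 500),
        l1_weight: float = 1e-4,
        l2_activity: float = 1e-3,
        learning_rate: float = 1e-6,
        epochs: int = 10,
        batch_size: int = 32,
        dropout: float = 0.5,
        hidden_activation: str = "tanh",
        output_activation: str = "sigmoid",
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.l1_weight = l1_weight
        self.l2_activity = l2_activity
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.dropout = dropout
        self.hidden_activation = hidden_activation
        self.output_activation = output_activation
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _validate(self, d: int) -> list[int]:
        hs = tuple(int(h) for h in self.hidden_sizes)
        if len(hs) % 2 != 1 or any(h <= 0 for h in hs):
            raise ContractError("hidden_sizes must be an odd-length tuple of positive ints")
        if hs[len(hs) // 2] >= d:
            raise ContractError("bottleneck size must be smaller than the input width")
        if not 0 <= self.dropout < 1:
            raise ContractError("dropout must lie in [0, 1)")
        return [d, *hs, d]

    def _init_params(self, layer_sizes, rng):
        self.coefs_, self.intercepts_ = [], []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.coefs_.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
            self.intercepts_.append(np.zeros(fan_out))

    def _forward(self, X, rng=None):
        """Return (raw activations, post-dropout activations) per layer.

        Dropout masks are drawn from ``rng`` when given (training mode);
        layer 0 is the input.
        """
        k = len(self.coefs_)
        raw = [np.asarray(X, dtype=float)]
        used = [raw[0]]
        keep = 1.0 - self.dropout
        for i in range(k):
            z = used[-1] @ self.coefs_[i].T + self.intercepts_[i]
            act = self.output_activation if i == k - 1 else self.hidden_activation
            a = _ACTIVATIONS[act](z)
            raw.append(a)
            if rng is not None and i < k - 1 and self.dropout > 0:
                mask = (rng.random(a.shape) < keep) / keep
                used.append(a * mask)
            else:
                used.append(a)
        return raw, used

    def _loss_and_grads(self, X, rng=None):
        """Total loss and parameter gradients on a batch (hand backprop)."""
        X = np.asarray(X, dtype=float)
        B = X.shape[0]
        k = len(self.coefs_)
        a_w, a_a = self.l1_weight, self.l2_activity
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            raw, used = self._forward(X, rng=rng)
            out = used[-1]
            recon = -np.sum(X * np.log(out) + (1 - X) * np.log(1 - out)) / B
            activity = sum(float(np.sum(a * a)) for a in used[1:]) / B
            l1 = sum(float(np.abs(W).sum()) for W in self.coefs_)
            loss = recon + a_a * activity + a_w * l1

            grads_W, grads_b = [None] * k, [None] * k
            # output layer: sigmoid + cross-entropy collapses to (out - X)
            delta = ((out - X) + 2 * a_a * (out * out) * (1 - out)) / B
            for i in range(k - 1, -1, -1):
                grads_W[i] = delta.T @ used[i] + a_w * np.sign(self.coefs_[i])
                grads_b[i] = delta.sum(axis=0)
                if i == 0:
                    break
                g = delta @ self.coefs_[i] + 2 * a_a * used[i] / B
                if rng is not None and self.dropout > 0:
                    # dropout mask is recoverable as the ratio used/raw
                    mask = np.where(
                        raw[i] != 0,
                        used[i] / np.where(raw[i] != 0, raw[i], 1.0), 0.0)
                    g = g * mask
                delta = g * (1 - raw[i] * raw[i])  # tanh'
        return loss, grads_W, grads_b

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ContractError("X must be 2-D (samples x features)")
        if np.any((X < 0) | (X > 1)) or not np.all(np.isfinite(X)):
            raise ContractError("autoencoder inputs must lie in [0, 1]")
        n, d = X.shape
        if n < self.batch_size:
            raise ContractError(
                f"need at least batch_size={self.batch_size} samples (got {n})"
            )
        layer_sizes = self._validate(d)
        rng = np.random.default_rng(self.random_state)
        self._init_params(layer_sizes, rng)
        self.layer_sizes_ = layer_sizes
        self.n_features_in_ = d
        lr = self.learning_rate

        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss, gW, gb = self._loss_and_grads(X[idx], rng=rng)
                if not np.isfinite(loss):
                    raise DivergenceError(epoch)
                batch_losses.append(loss)
                if lr:
                    for i in range(len(self.coefs_)):
                        self.coefs_[i] -= lr * gW[i]
                        self.intercepts_[i] -= lr * gb[i]
            self.loss_curve_.append(float(np.mean(batch_losses)))
        return self

    def total_loss(self, X) -> float:
        """Regularized loss on a batch, dropout disabled."""
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ContractError("batch width does not match the fitted model")
        loss, _, _ = self._loss_and_grads(X, rng=None)
        return float(loss)

    @property
    def bottleneck_layer_(self) -> int:
        return (len(self.hidden_sizes) + 1) // 2

    def transform(self, X):
        """Bottleneck activations, deterministic (no dropout)."""
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ContractError(
                f"input width {X.shape[1]} != fitted width {self.n_features_in_}"
            )
        _, used = self._forward(X, rng=None)
        out = used[self.bottleneck_layer_]
        return out[0] if single else out

    def reconstruct(self, X):
        check_is_fitted(self, "coefs_")
        _, used = self._forward(np.atleast_2d(np.asarray(X, dtype=float)), rng=None)
        return used[-1]

    # -- persistence ------------------------------------------------------

    def save(self, directory) -> None:
        """Checkpoint (weights + config + loss trajectory) to a directory."""
        check_is_fitted(self, "coefs_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "layer_sizes": self.layer_sizes_,
            "loss_curve": self.loss_curve_,
            "n_layers": len(self.coefs_),
        }
        (directory / "model.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
        for i, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            np.save(directory / f"W_{i}.npy", W)
            np.save(directory / f"b_{i}.npy", b)

    @classmethod
    def load(cls, directory) -> "Autoencoder":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        params = dict(meta["params"])
        params["hidden_sizes"] = tuple(params["hidden_sizes"])
        model = cls(**params)
        model.coefs_ = [np.load(directory / f"W_{i}.npy") for i in range(meta["n_layers"])]
        model.intercepts_ = [np.load(directory / f"b_{i}.npy") for i in range(meta["n_layers"])]
        model.layer_sizes_ = meta["layer_sizes"]
        model.loss_curve_ = meta["loss_curve"]
        model.n_features_in_ = model.layer_sizes_[0]
        return model


def total_loss(model: Autoencoder, batch) -> float:
    """Functional wrapper over :meth:`Autoencoder.total_loss`."""
    return model.total_loss(batch)


def encode(model: Autoencoder, data: pd.DataFrame) -> pd.DataFrame:
    """Encode a feature-by-sample matrix into named latent features.

    Returns a samples-by-latent DataFrame with columns ``AE_001`` ...;
    row order follows the input sample order.
    """
    values = model.transform(data.T.to_numpy(dtype=float))
    width = max(3, len(str(values.shape[1])))
    names = [f"AE_{i + 1:0{width}d}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=data.columns, columns=names)
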