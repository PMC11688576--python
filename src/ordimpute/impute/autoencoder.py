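"""Autoencoder imputation.

A small symmetric multilayer perceptron (p -> 7 -> 5 -> 3 -> 5 -> 7 -> p,
ReLU on the hidden layers, linear bottleneck and output) is trained
full-batch with Adam to reconstruct the incomplete matrix.  Columns are
standardized with observed means/sds and missing cells pre-filled with
zero in the standardized space (i.e. the column mean).  By default the
reconstruction loss is restricted to observed cells; ``loss="full"``
additionally scores the artificial zeros at missing cells, reproducing
the simpler zero-target training variant.

Missing cells are read off the trained network's output and
de-standardized; observed cells pass through unchanged.
"""

from __future__ import annotations

import numpy as np

from ..nn import Adam, Tensor, matmul, relu
from .base import BaseImputer, check_incomplete_matrix

__all__ = ["AutoencoderImputer", "autoencoder_impute"]


def _init_linear(rng, fan_in: int, fan_out: int) -> tuple[Tensor, Tensor]:
    # Glorot-uniform weights, zero biases
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    w = Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)), requires_grad=True)
    b = Tensor(np.zeros(fan_out), requires_grad=True)
    return w, b


class AutoencoderImputer(BaseImputer):
    """Symmetric MLP autoencoder imputer.

    Parameters
    ----------
    hidden_dims : tuple of int
        Encoder hidden widths, mirrored in the decoder; default (7, 5).
    bottleneck : int
        Width of the linear central layer, default 3.
    lr : float
        Adam learning rate, default 1e-3.
    epochs : int
        Full-batch training epochs, default 100.
    loss : {"observed", "full"}
        Score reconstruction on observed cells only (default) or on the
        whole zero-filled matrix.
    random_state : int or None
        Seeds the weight initialization.

    Attributes
    ----------
    loss_trace_ : training MSE per epoch.
    """

    def __init__(
        self,
        hidden_dims: tuple[int, ...] = (7, 5),
        bottleneck: int = 3,
        lr: float = 1e-3,
        epochs: int = 100,
        loss: str = "observed",
        random_state: int | None = None,
    ):
        self.hidden_dims = hidden_dims
        self.bottleneck = bottleneck
        self.lr = lr
        self.epochs = epochs
        self.loss = loss
        self.random_state = random_state

    def _check_config(self) -> None:
        dims = tuple(self.hidden_dims) + (self.bottleneck,)
        if any(d < 1 for d in dims):
            raise ValueError("layer widths must be positive")
        if any(b >= a for a, b in zip(dims, dims[1:])):
            raise ValueError(
                f"widths must decrease toward the bottleneck, got {dims}"
            )
        if self.loss not in ("observed", "full"):
            raise ValueError("loss must be 'observed' or 'full'")

    def _forward(self, x: Tensor) -> Tensor:
        h = x
        n_hidden = len(self.hidden_dims)
        for layer, (w, b) in enumerate(self._layers):
            h = matmul(h, w) + b
            # ReLU on encoder/decoder hidden layers; bottleneck (index
            # n_hidden) and output (last) stay linear
            is_last = layer == len(self._layers) - 1
            if layer != n_hidden and not is_last:
                h = relu(h)
        return h

    def _fit(self, X: np.ndarray) -> None:
        self._check_config()
        rng = np.random.default_rng(self.random_state)
        p = X.shape[1]
        widths = [p, *self.hidden_dims, self.bottleneck,
                  *reversed(self.hidden_dims), p]
        self._layers = [
            _init_linear(rng, a, b) for a, b in zip(widths, widths[1:])
        ]
        params = [t for pair in self._layers for t in pair]

        self._col_mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0)
        sd[sd == 0] = 1.0
        self._col_sd = sd
        z = (X - self._col_mean) / self._col_sd
        observed = ~np.isnan(X)
        z = np.where(observed, z, 0.0)

        target = Tensor(z)
        weight = observed.astype(float) if self.loss == "observed" else np.ones_like(z)
        denom = float(weight.sum())
        opt = Adam(params, lr=self.lr)
        trace: list[float] = []
        for epoch in range(self.epochs):
            out = self._forward(Tensor(z))
            loss = ((out - target).square() * weight).sum() / denom
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(float(loss.data))
        self.loss_trace_ = trace

    def _transform(self, X: np.ndarray) -> np.ndarray:
        z = (X - self._col_mean) / self._col_sd
        z = np.where(np.isnan(X), 0.0, z)
        recon = self._forward(Tensor(z)).data
        out = X.copy()
        miss = np.isnan(X)
        recon_raw = recon * self._col_sd + self._col_mean
        out[miss] = recon_raw[miss]
        return out


def autoencoder_impute(X, epochs: int = 100, seed: int | None = None, **kwargs) -> np.ndarray:
    """Functional one-shot autoencoder imputation."""
    X = check_incomplete_matrix(X)
    imp = AutoencoderImputer(epochs=epochs, random_state=seed, **kwargs)
    return imp.fit(X).transform(X)
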