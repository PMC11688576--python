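"""Re-masking masked-autoencoding transformer imputation.

Each cell of the table becomes a token: value times a learned per-feature
embedding direction plus a learned per-feature positional embedding.
During training every row re-masks a random subset of its *observed*
cells (ratio ``mask_ratio``) on top of the naturally missing ones; a
pre-norm transformer encoder attends only over the visible tokens, the
decoder sees encoder outputs at visible positions and a shared learned
mask token (plus positional embedding) at hidden positions, and a linear
head reconstructs a scalar per cell.  The MSE loss is taken over the
re-masked observed cells only — the positions whose ground truth is known
but hidden from the encoder.  At imputation time all observed cells are
visible and predictions are read at the naturally missing positions.

Features are min-max scaled to [0, 1] on observed values before
tokenization and un-scaled afterwards.
"""

from __future__ import annotations

import numpy as np

from ..nn import Adam, Tensor, layer_norm, linear, matmul, relu, softmax
from .base import BaseImputer, check_incomplete_matrix

__all__ = ["ReMaskerImputer", "remask_select"]

_NEG = -1e9  # additive attention bias hiding masked keys


def remask_select(
    observed_mask: np.ndarray, ratio: float, seed=None
) -> np.ndarray:
    """Uniformly select round(ratio * n_observed) observed positions.

    ``seed`` may be an integer or a numpy Generator.  Naturally missing
    positions are never selected; with no observed position the selection
    is empty.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    observed_mask = np.asarray(observed_mask, dtype=bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.zeros_like(observed_mask)
    obs_idx = np.flatnonzero(observed_mask)
    k = int(round(ratio * obs_idx.size))
    if k:
        out[rng.choice(obs_idx, size=k, replace=False)] = True
    return out


def _linear(rng, fan_in: int, fan_out: int) -> tuple[Tensor, Tensor]:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    w = Tensor(
        rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(np.float32),
        requires_grad=True,
    )
    b = Tensor(np.zeros(fan_out, dtype=np.float32), requires_grad=True)
    return w, b


def _param(rng, *shape) -> Tensor:
    return Tensor(
        (rng.standard_normal(shape) * 0.02).astype(np.float32), requires_grad=True
    )


def _norm_pair(dim: int) -> tuple[Tensor, Tensor]:
    return (
        Tensor(np.ones(dim, dtype=np.float32), requires_grad=True),
        Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True),
    )


class _Block:
    """One pre-norm transformer block: x + MHSA(LN(x)), x + FF(LN(x))."""

    def __init__(self, rng, dim: int, n_heads: int, ff_mult: int = 4):
        self.dim = dim
        self.n_heads = n_heads
        self.dh = dim // n_heads
        self.ln1_g, self.ln1_b = _norm_pair(dim)
        self.wq = _linear(rng, dim, dim)
        self.wk = _linear(rng, dim, dim)
        self.wv = _linear(rng, dim, dim)
        self.wo = _linear(rng, dim, dim)
        self.ln2_g, self.ln2_b = _norm_pair(dim)
        self.ff1 = _linear(rng, dim, ff_mult * dim)
        self.ff2 = _linear(rng, ff_mult * dim, dim)

    def params(self) -> list[Tensor]:
        out = [self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b]
        for pair in (self.wq, self.wk, self.wv, self.wo, self.ff1, self.ff2):
            out.extend(pair)
        return out

    def __call__(self, x: Tensor, key_bias: np.ndarray | None) -> Tensor:
        n, p, e = x.data.shape
        h, dh = self.n_heads, self.dh

        def heads(t: Tensor) -> Tensor:
            return t.reshape(n, p, h, dh).transpose(0, 2, 1, 3)

        u = layer_norm(x, self.ln1_g, self.ln1_b)
        q = heads(linear(u, *self.wq))
        k = heads(linear(u, *self.wk))
        v = heads(linear(u, *self.wv))
        scores = matmul(q, k.transpose(0, 1, 3, 2)) * np.float32(1.0 / np.sqrt(dh))
        attn = softmax(scores, bias=key_bias)
        ctx = matmul(attn, v).transpose(0, 2, 1, 3).reshape(n, p, e)
        x = x + linear(ctx, *self.wo)

        u = layer_norm(x, self.ln2_g, self.ln2_b)
        ff = linear(relu(linear(u, *self.ff1)), *self.ff2)
        return x + ff


class ReMaskerImputer(BaseImputer):
    """Masked-autoencoding transformer imputer.

    Parameters
    ----------
    embed_dim : int
        Token embedding width (divisible by ``n_heads``), default 32.
    encoder_depth, decoder_depth : int
        Transformer blocks in encoder/decoder, defaults 4 and 2.
    n_heads : int
        Attention heads, default 4.
    mask_ratio : float
        Fraction of observed cells re-masked per row per epoch, default 0.5.
    epochs : int
        Training epochs (full batch), default 300.
    lr : float
        Adam learning rate, default 1e-3.
    ff_mult : int
        Width multiplier of the feed-forward sublayers, default 4.
    random_state : int or None
        Seeds initialization and the per-epoch re-masking.

    Attributes
    ----------
    loss_trace_ : training loss per epoch (re-masked cells only).
    """

    def __init__(
        self,
        embed_dim: int = 32,
        encoder_depth: int = 4,
        decoder_depth: int = 2,
        n_heads: int = 4,
        mask_ratio: float = 0.5,
        epochs: int = 300,
        lr: float = 1e-3,
        ff_mult: int = 4,
        random_state: int | None = None,
    ):
        self.embed_dim = embed_dim
        self.encoder_depth = encoder_depth
        self.decoder_depth = decoder_depth
        self.n_heads = n_heads
        self.mask_ratio = mask_ratio
        self.epochs = epochs
        self.lr = lr
        self.ff_mult = ff_mult
        self.random_state = random_state

    # -- model pieces ----------------------------------------------------
    def _build(self, rng, p: int) -> list[Tensor]:
        e = self.embed_dim
        self._feat_dir = _param(rng, p, e)
        self._pos_enc = _param(rng, p, e)
        self._pos_dec = _param(rng, p, e)
        self._mask_token = _param(rng, e)
        self._enc_blocks = [
            _Block(rng, e, self.n_heads, self.ff_mult)
            for _ in range(self.encoder_depth)
        ]
        self._dec_blocks = [
            _Block(rng, e, self.n_heads, self.ff_mult)
            for _ in range(self.decoder_depth)
        ]
        self._enc_ng, self._enc_nb = _norm_pair(e)
        self._dec_ng, self._dec_nb = _norm_pair(e)
        self._head = _linear(rng, e, 1)
        params = [
            self._feat_dir, self._pos_enc, self._pos_dec, self._mask_token,
            self._enc_ng, self._enc_nb, self._dec_ng, self._dec_nb,
            *self._head,
        ]
        for blk in self._enc_blocks + self._dec_blocks:
            params.extend(blk.params())
        return params

    def _forward(self, z: np.ndarray, visible: np.ndarray) -> Tensor:
        """Predict all p scalars per row; ``visible`` marks encoder inputs."""
        n, p = z.shape
        zc = Tensor(np.where(visible, z, 0.0)[:, :, None].astype(np.float32))
        t = zc * self._feat_dir + self._pos_enc
        key_bias = np.where(visible, 0.0, _NEG)[:, None, None, :].astype(np.float32)
        for blk in self._enc_blocks:
            t = blk(t, key_bias)
        enc = layer_norm(t, self._enc_ng, self._enc_nb)
        vis = visible.astype(np.float32)[:, :, None]
        d = enc * vis + self._mask_token * (np.float32(1.0) - Tensor(vis)) + self._pos_dec
        for blk in self._dec_blocks:
            d = blk(d, None)
        d = layer_norm(d, self._dec_ng, self._dec_nb)
        pred = matmul(d, self._head[0]) + self._head[1]
        return pred.reshape(n, p)

    # -- sklearn surface ---------------------------------------------------
    def _fit(self, X: np.ndarray) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim={self.embed_dim} not divisible by n_heads={self.n_heads}"
            )
        if not 0.0 < self.mask_ratio < 1.0:
            raise ValueError("mask_ratio must lie in (0, 1)")
        rng = np.random.default_rng(self.random_state)
        n, p = X.shape
        observed = ~np.isnan(X)
        self._xmin = np.nanmin(X, axis=0)
        span = np.nanmax(X, axis=0) - self._xmin
        span[span == 0] = 1.0
        self._span = span
        z = np.where(observed, (X - self._xmin) / span, 0.0)

        params = self._build(rng, p)
        opt = Adam(params, lr=self.lr)
        k_per_row = np.round(self.mask_ratio * observed.sum(axis=1)).astype(int)
        target = Tensor(z.astype(np.float32))
        trace: list[float] = []
        for epoch in range(self.epochs):
            # vectorized per-row uniform re-mask of observed cells
            keys = rng.random((n, p))
            keys[~observed] = np.inf
            rank = np.argsort(np.argsort(keys, axis=1, kind="stable"), axis=1)
            remask = (rank < k_per_row[:, None]) & observed
            visible = observed & ~remask
            pred = self._forward(z, visible)
            w = remask.astype(np.float32)
            denom = max(w.sum(), 1.0)
            loss = ((pred - target).square() * w).sum() / denom
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
        observed = ~np.isnan(X)
        z = np.where(observed, (X - self._xmin) / self._span, 0.0)
        pred = self._forward(z, observed).data
        out = X.copy()
        miss = ~observed
        out[miss] = (pred * self._span + self._xmin)[miss]
        return out


def remasker_impute(X, seed: int | None = None, **kwargs) -> np.ndarray:
    """Functional one-shot ReMasker imputation."""
    X = check_incomplete_matrix(X)
    imp = ReMaskerImputer(random_state=seed, **kwargs)
    return imp.fit(X).transform(X)
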