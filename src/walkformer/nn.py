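"""Transformer building blocks on top of the numpy autodiff core.

The encoder follows the compact graph-transformer recipe: sinusoidal
positional encodings, multi-head scaled dot-product self-attention with
bias-free Q/K/V projections and concatenated heads, a position-wise two-layer
ReLU feed-forward network, and post-norm residual connections around each
sublayer. There is no output projection after head concatenation: the
attention sublayer is exactly softmax(QK^T/sqrt(d_k))V per head.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, dropout, layer_norm, relu, softmax

__all__ = [
    "positional_encoding",
    "positional_encoding_matrix",
    "self_attention",
    "feed_forward",
    "EncoderBlock",
    "xavier_uniform",
]


def positional_encoding(pos: int, e: int) -> np.ndarray:
    """Sinusoidal encoding of one position.

    Coordinate ``i`` is ``sin(pos / 10000**(i/e))`` for even ``i`` and
    ``cos(pos / 10000**((i-1)/e))`` for odd ``i``. Note the exponent steps by
    1/e per coordinate pair index, so even/odd coordinate pairs share a
    wavelength through the (i-1) in the odd case.
    """
    if pos < 0 or e < 1:
        raise ValueError("pos must be >= 0 and e >= 1")
    i = np.arange(e)
    exponent = np.where(i % 2 == 0, i, i - 1) / e
    angle = pos / np.power(10000.0, exponent)
    return np.where(i % 2 == 0, np.sin(angle), np.cos(angle))


def positional_encoding_matrix(length: int, e: int) -> np.ndarray:
    """Stack of encodings for positions 0..length-1, shape (length, e)."""
    return np.stack([positional_encoding(p, e) for p in range(length)])


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def self_attention(
    H: Tensor,
    Wq: Tensor,
    Wk: Tensor,
    Wv: Tensor,
    n_heads: int,
    key_mask: np.ndarray | None = None,
) -> Tensor:
    """Multi-head scaled dot-product self-attention, heads concatenated.

    ``H`` is (..., L, d); ``Wq/Wk/Wv`` are (d, d) and are split into
    ``n_heads`` column blocks of width ``d_k = d / n_heads``. ``key_mask`` is
    a boolean (..., L) array marking keys to exclude (padding); excluded keys
    receive -1e9 before the softmax.
    """
    d = H.shape[-1]
    if d % n_heads != 0:
        raise ValueError(f"width {d} not divisible by {n_heads} heads")
    dk = d // n_heads
    Q, K, V = H @ Wq, H @ Wk, H @ Wv

    lead = H.shape[:-2]
    L = H.shape[-2]

    def split(x: Tensor) -> Tensor:
        # (..., L, d) -> (..., n_heads, L, dk)
        x = x.reshape(*lead, L, n_heads, dk)
        axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        return x.transpose(*axes)

    Qh, Kh, Vh = split(Q), split(K), split(V)
    scores = (Qh @ Kh.transpose(*range(Qh.ndim - 2), Qh.ndim - 1, Qh.ndim - 2)) * (
        1.0 / np.sqrt(dk)
    )
    additive = None
    if key_mask is not None:
        # broadcast over heads and query positions: (..., 1, 1, L)
        additive = np.where(key_mask, -1e9, 0.0)[..., None, None, :]
    attn = softmax(scores, additive_mask=additive)
    out = attn @ Vh  # (..., n_heads, L, dk)
    axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
    return out.transpose(*axes).reshape(*lead, L, d)


def feed_forward(x: Tensor, W1: Tensor, b1: Tensor, W2: Tensor, b2: Tensor) -> Tensor:
    """Position-wise ReLU(x W1 + b1) W2 + b2."""
    return relu(x @ W1 + b1) @ W2 + b2


class EncoderBlock:
    """Self-attention + feed-forward sublayers with post-norm residuals."""

    def __init__(self, rng: np.random.Generator, d: int, n_heads: int, ffn_hidden: int):
        self.n_heads = n_heads
        self.Wq = Tensor(xavier_uniform(rng, d, d), requires_grad=True)
        self.Wk = Tensor(xavier_uniform(rng, d, d), requires_grad=True)
        self.Wv = Tensor(xavier_uniform(rng, d, d), requires_grad=True)
        self.W1 = Tensor(xavier_uniform(rng, d, ffn_hidden), requires_grad=True)
        self.b1 = Tensor(np.zeros(ffn_hidden), requires_grad=True)
        self.W2 = Tensor(xavier_uniform(rng, ffn_hidden, d), requires_grad=True)
        self.b2 = Tensor(np.zeros(d), requires_grad=True)
        self.ln1_g = Tensor(np.ones(d), requires_grad=True)
        self.ln1_b = Tensor(np.zeros(d), requires_grad=True)
        self.ln2_g = Tensor(np.ones(d), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(d), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [
            self.Wq, self.Wk, self.Wv,
            self.W1, self.b1, self.W2, self.b2,
            self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b,
        ]

    def __call__(
        self,
        h: Tensor,
        key_mask: np.ndarray | None = None,
        drop_rate: float = 0.0,
        drop_rng: np.random.Generator | None = None,
    ) -> Tensor:
        a = self_attention(h, self.Wq, self.Wk, self.Wv, self.n_heads, key_mask=key_mask)
        h = layer_norm(h + dropout(a, drop_rate, drop_rng), self.ln1_g, self.ln1_b)
        f = feed_forward(h, self.W1, self.b1, self.W2, self.b2)
        h = layer_norm(h + dropout(f, drop_rate, drop_rng), self.ln2_g, self.ln2_b)
        return h
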