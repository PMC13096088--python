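"""Differentiable building blocks on top of ``autograd.numpy``.

All functions accept and return plain (autograd-boxed) arrays and never
mutate their inputs. Feature maps use channels-last layout ``(..., H, W, C)``.
"""

from __future__ import annotations

import autograd.numpy as anp


def linear(params, x):
    """Affine map ``x @ W + b`` over the last axis.

    ``params`` is a dict with ``"W"`` of shape (in, out) and ``"b"`` of
    shape (out,).
    """
    return anp.matmul(x, params["W"]) + params["b"]


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)  # numerically stable form


def relu(x):
    return anp.maximum(x, 0.0)


def gelu(x):
    """tanh-approximate GELU."""
    return 0.5 * x * (1.0 + anp.tanh(0.7978845608028654 * (x + 0.044715 * x ** 3)))


def softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def layer_norm(params, x, eps: float = 1e-5):
    """Normalize the last axis; ``params`` holds ``"gamma"`` and ``"beta"``."""
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.var(x, axis=-1, keepdims=True)
    xhat = (x - mu) / anp.sqrt(var + eps)
    return xhat * params["gamma"] + params["beta"]


def conv2d_1x1(params, x):
    """1x1 convolution on (..., H, W, C_in) -> (..., H, W, C_out).

    Equivalent to a per-pixel linear map over channels.
    """
    return anp.matmul(x, params["W"]) + params["b"]


def conv2d_3x3(params, x):
    """3x3 same-padded convolution on (B, H, W, C_in).

    ``params["W"]`` has shape (3, 3, C_in, C_out). Implemented as a sum of
    nine shifted 1x1 products, which keeps everything inside autograd's
    primitive set.
    """
    W = params["W"]
    pad_width = ((0, 0), (1, 1), (1, 1), (0, 0))
    xp = anp.pad(x, pad_width, mode="constant")
    H, Wd = x.shape[1], x.shape[2]
    out = 0.0
    for di in range(3):
        for dj in range(3):
            patch = xp[:, di:di + H, dj:dj + Wd, :]
            out = out + anp.matmul(patch, W[di, dj])
    return out + params["b"]


def multi_head_attention(params, x, n_heads: int):
    """Scaled dot-product multi-head self-attention over (B, N, d).

    Attention weights for token t over tokens tau are
    ``softmax_tau(Q_t K_tau^T / sqrt(d_head))``; the weighted values are
    concatenated across heads and linearly projected.
    """
    B, N, d = x.shape
    dh = d // n_heads
    q = linear(params["q"], x)
    k = linear(params["k"], x)
    v = linear(params["v"], x)

    def split(t):
        t = anp.reshape(t, (B, N, n_heads, dh))
        return anp.transpose(t, (0, 2, 1, 3))  # (B, h, N, dh)

    q, k, v = split(q), split(k), split(v)
    scores = anp.matmul(q, anp.transpose(k, (0, 1, 3, 2))) / anp.sqrt(dh)
    attn = softmax(scores, axis=-1)
    out = anp.matmul(attn, v)  # (B, h, N, dh)
    out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (B, N, d))
    return linear(params["proj"], out), attn


def feed_forward(params, x):
    """Two-layer position-wise FFN with GELU."""
    return linear(params["fc2"], gelu(linear(params["fc1"], x)))


def transformer_block(params, x, n_heads: int):
    """Pre-norm transformer encoder block; returns (output, attention)."""
    h, attn = multi_head_attention(params["attn"], layer_norm(params["ln1"], x), n_heads)
    x = x + h
    x = x + feed_forward(params["ffn"], layer_norm(params["ln2"], x))
    return x, attn


def global_avg_pool(x):
    """(B, H, W, C) -> (B, C) spatial mean."""
    return anp.mean(x, axis=(1, 2))


def global_max_pool(x):
    """(B, H, W, C) -> (B, C) spatial max."""
    return anp.max(anp.max(x, axis=1), axis=1)
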