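"""The cross-modal and spatial-temporal attention operations.

``env_guided_attention`` gates visual channels by a product of a visual
channel-attention factor and an environmental regulatory factor, then
applies a 1x1-conv spatial map and a 1x1-conv residual branch.
``spatial_attention`` reweights each frame by a 3x3-conv saliency map
derived from channel-pooled descriptors. ``temporal_attention`` runs
bidirectional stacks of multi-head softmax attention blocks over the
per-step pooled token sequence.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from greensentry.nn import functional as F
from greensentry.nn import init as nninit


# ---------------------------------------------------------------------------
# environment-guided visual attention
# ---------------------------------------------------------------------------

def init_env_guided_params(rng: np.random.Generator, channels: int, env_hidden: int) -> dict:
    return {
        "channel": nninit.linear_params(rng, 2 * channels, channels),      # W_c
        "env_fc1": nninit.linear_params(rng, env_hidden, env_hidden),      # W_e (two-layer)
        "env_fc2": nninit.linear_params(rng, env_hidden, channels),
        "spatial": nninit.linear_params(rng, channels, 1),                 # 1x1 conv -> A_s
        "residual": {"W": nninit.xavier_uniform(rng, channels, channels)}, # bias-free 1x1
    }


def env_guided_attention(params, feat, s, use_env_guidance: bool = True):
    """Modulate visual features (B, H, W, C) by environmental state s (B, E).

    Returns a dict with:
      ``modulated`` -- pre-residual gated features ``F * a_c * m_c``
      ``output``    -- F + 1x1conv(modulated * A_s), the stage output
      ``a_c``, ``m_c``, ``A_s`` -- diagnostic attention factors
    """
    if feat.shape[-1] != params["channel"]["W"].shape[1]:
        raise ValueError("feature channel count does not match module parameters")
    f_avg = F.global_avg_pool(feat)                       # (B, C)
    f_max = F.global_max_pool(feat)                       # (B, C)
    a_c = F.sigmoid(F.linear(params["channel"], anp.concatenate([f_avg, f_max], axis=-1)))
    if use_env_guidance:
        m_c = F.sigmoid(F.linear(params["env_fc2"], F.relu(F.linear(params["env_fc1"], s))))
    else:
        m_c = anp.ones_like(a_c)
    gate = (a_c * m_c)[:, None, None, :]                  # broadcast over H, W
    modulated = feat * gate
    a_s = F.sigmoid(F.conv2d_1x1(params["spatial"], modulated))  # (B, H, W, 1)
    branch = anp.matmul(modulated * a_s, params["residual"]["W"])
    return {
        "modulated": modulated,
        "output": feat + branch,
        "a_c": a_c,
        "m_c": m_c,
        "A_s": a_s[..., 0],
    }


# ---------------------------------------------------------------------------
# per-frame spatial attention
# ---------------------------------------------------------------------------

def init_spatial_params(rng: np.random.Generator) -> dict:
    return {"conv": nninit.conv3x3_params(rng, 2, 1)}


def spatial_attention(params, feat):
    """Saliency-reweight a feature map (B, H, W, C).

    Channel-wise average and max pooling give two (B, H, W) maps; their
    concatenation passes through a 3x3 convolution and sigmoid to give
    ``A_t``; the output is ``feat * A_t``. Returns (S_t, A_t).
    """
    f_avg = anp.mean(feat, axis=-1, keepdims=True)
    f_max = anp.max(feat, axis=-1, keepdims=True)
    desc = anp.concatenate([f_avg, f_max], axis=-1)       # (B, H, W, 2)
    a_t = F.sigmoid(F.conv2d_3x3(params["conv"], desc))   # (B, H, W, 1)
    return feat * a_t, a_t[..., 0]


# ---------------------------------------------------------------------------
# bidirectional temporal attention
# ---------------------------------------------------------------------------

def init_temporal_params(rng: np.random.Generator, d: int, n_blocks: int,
                         ffn_mult: int) -> dict:
    return {
        "forward": [nninit.transformer_block_params(rng, d, ffn_mult * d)
                    for _ in range(n_blocks)],
        "backward": [nninit.transformer_block_params(rng, d, ffn_mult * d)
                     for _ in range(n_blocks)],
        "fuse": nninit.linear_params(rng, 2 * d, d),
    }


def temporal_attention(params, z, n_heads: int):
    """Bidirectional temporal encoding of per-step embeddings z (B, T, d).

    Forward and backward encoders are independent stacks of pre-norm
    multi-head attention blocks (softmax(Q K^T / sqrt(d_head)) V) with
    4d-wide FFNs; their outputs are concatenated along features and fused
    linearly to (B, T, d). Returns (H, attention_weights) where the
    weights are the first forward block's (B, heads, T, T) map.
    """
    if z.shape[1] < 1:
        raise ValueError("temporal attention requires T >= 1")
    x_f = z
    attn_maps = []
    for block in params["forward"]:
        x_f, attn = F.transformer_block(block, x_f, n_heads)
        attn_maps.append(attn)
    x_b = z[:, ::-1, :]
    for block in params["backward"]:
        x_b, _ = F.transformer_block(block, x_b, n_heads)
    x_b = x_b[:, ::-1, :]
    fused = F.linear(params["fuse"], anp.concatenate([x_f, x_b], axis=-1))
    return fused, attn_maps[0]
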