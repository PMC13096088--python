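"""Hierarchical windowed-attention visual backbone.

Patch embedding followed by three stages; each stage halves the spatial
resolution via patch merging and applies a window-based transformer
block, producing feature maps at 1/8, 1/16 and 1/32 of the input
resolution with widening channel counts.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from greensentry.nn import functional as F
from greensentry.nn import init as nninit
from greensentry.model.config import ModelConfig


def init_backbone_params(rng: np.random.Generator, config: ModelConfig) -> dict:
    p = config.patch_size
    c_pe = max(4, config.stage_channels[0] // 2)
    params = {
        "patch_embed": nninit.linear_params(rng, p * p * 3, c_pe),
        "stages": [],
    }
    c_prev = c_pe
    for c in config.stage_channels:
        params["stages"].append({
            "merge": nninit.linear_params(rng, 4 * c_prev, c),
            "block": nninit.transformer_block_params(rng, c, 4 * c),
        })
        c_prev = c
    return params


def _patch_embed(params, images, patch: int):
    """(B, H, W, 3) -> (B, H/p, W/p, C_pe) by non-overlapping patch flattening."""
    B, H, W, _ = images.shape
    x = anp.reshape(images, (B, H // patch, patch, W // patch, patch, 3))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    x = anp.reshape(x, (B, H // patch, W // patch, patch * patch * 3))
    return F.linear(params["patch_embed"], x)


def _patch_merge(params, x):
    """(B, h, w, C) -> (B, h/2, w/2, C_out): 2x2 neighbourhood concat + linear."""
    B, h, w, C = x.shape
    x = anp.reshape(x, (B, h // 2, 2, w // 2, 2, C))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    x = anp.reshape(x, (B, h // 2, w // 2, 4 * C))
    return F.linear(params, x)


def _window_block(params, x, window: int, n_heads: int):
    """Apply a transformer block within non-overlapping spatial windows."""
    B, h, w, C = x.shape
    win = min(window, h, w)
    while h % win != 0 or w % win != 0:  # largest feasible window
        win -= 1
    nh, nw = h // win, w // win
    t = anp.reshape(x, (B, nh, win, nw, win, C))
    t = anp.transpose(t, (0, 1, 3, 2, 4, 5))
    t = anp.reshape(t, (B * nh * nw, win * win, C))
    t, _ = F.transformer_block(params, t, n_heads)
    t = anp.reshape(t, (B, nh, nw, win, win, C))
    t = anp.transpose(t, (0, 1, 3, 2, 4, 5))
    return anp.reshape(t, (B, h, w, C))


def forward_stage(params_stage, config: ModelConfig, x):
    """One backbone stage: patch merging then a windowed transformer block."""
    x = _patch_merge(params_stage["merge"], x)
    return _window_block(params_stage["block"], x, config.window_size,
                         config.backbone_heads)


def forward_backbone(params, config: ModelConfig, images):
    """Run the plain backbone over (B, H, W, 3) images.

    Returns the list of per-stage feature maps, shaped
    (B, H/8, W/8, C1), (B, H/16, W/16, C2), (B, H/32, W/32, C3) for the
    default three-stage configuration.
    """
    x = _patch_embed(params, images, config.patch_size)
    outputs = []
    for stage in params["stages"]:
        x = forward_stage(stage, config, x)
        outputs.append(x)
    return outputs
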