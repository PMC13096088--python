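"""The full dual-branch network: construction, forward pass, checkpoints.

Per frame, each backbone stage output is modulated by environment-guided
channel gating and spatial saliency before feeding the next stage; the
final-stage features of the T frames are pooled per step and fused by the
bidirectional temporal encoder, whose last-step representation, combined
with pooled high-level visual semantics, drives the classification head.
Auxiliary heads at intermediate scales support deep supervision, and the
projected embeddings ``z_env`` / ``z_vis`` feed the alignment loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import autograd.numpy as anp
import numpy as np
from autograd.misc.flatten import flatten

from greensentry.nn import functional as F
from greensentry.nn import init as nninit
from greensentry.model import attention as attn
from greensentry.model import backbone as bb
from greensentry.model.config import ModelConfig


@dataclass
class ModelOutputs:
    """Everything the loss and the evaluation suite need from one forward pass."""

    stage_probs: np.ndarray                  # (B, n_classes), rows sum to 1
    spatial_map: Optional[np.ndarray]        # (B, H', W') in (0,1) or None
    aux_outputs: dict                        # stage index -> (B, n_classes)
    z_env: np.ndarray                        # (B, D)
    z_vis: np.ndarray                        # (B, D)
    attention_maps: dict = field(default_factory=dict)


def init_params(config: ModelConfig) -> dict:
    """Xavier-uniform initialized parameter tree for the full network."""
    rng = np.random.default_rng(config.seed)
    d = config.embed_dim
    params = {
        "backbone": bb.init_backbone_params(rng, config),
        "env_embed": nninit.linear_params(rng, config.env_dim, config.env_hidden),
        "env_hierarchy": [nninit.linear_params(rng, config.env_hidden, config.env_hidden)
                          for _ in range(config.n_stages)],
        "guided": [attn.init_env_guided_params(rng, c, config.env_hidden)
                   for c in config.stage_channels],
        "spatial": [attn.init_spatial_params(rng) for _ in config.stage_channels],
        "token_proj": nninit.linear_params(rng, config.stage_channels[-1], d),
        "temporal": attn.init_temporal_params(rng, d, config.n_temporal_blocks,
                                              config.ffn_mult),
        "vis_sem": nninit.linear_params(rng, config.stage_channels[-1], d),
        "cls_head": nninit.linear_params(rng, 2 * d, config.n_classes),
        "aux_heads": {str(s): nninit.linear_params(rng, config.stage_channels[s],
                                                   config.n_classes)
                      for s in config.aux_scales},
        "z_vis_proj": nninit.linear_params(rng, config.stage_channels[-1],
                                           config.align_dim),
        "z_env_proj": nninit.linear_params(rng, config.env_hidden, config.align_dim),
    }
    if config.use_spatial_head:
        params["spatial_head"] = nninit.linear_params(rng, config.stage_channels[0], 1)
    return params


def embed_environment(params, env_vector, config: ModelConfig):
    """Sensor branch: base embedding s plus the per-stage hierarchy S^(l).

    ``env_vector`` is (..., 4). Returns (s, [S^(1) ... S^(L)]), each stage
    representation sized ``env_hidden`` (the guided module's two-layer
    mapping aligns it to the stage's channel count).
    """
    s = F.linear(params["env_embed"], env_vector)
    hierarchy = []
    h = s
    for layer in params["env_hierarchy"]:
        h = anp.tanh(F.linear(layer, h))
        hierarchy.append(h)
    return s, hierarchy


def visual_backbone(params, config: ModelConfig, images):
    """Plain hierarchical backbone features for (B, H, W, 3) images."""
    return bb.forward_backbone(params["backbone"], config, images)


def forward(params, config: ModelConfig, images, env_vectors,
            use_env_guidance: Optional[bool] = None) -> ModelOutputs:
    """Forward a batch of sequences.

    ``images``: (B, T, H, W, 3) floats in [0, 1];
    ``env_vectors``: (B, T, 4) aligned normalized environmental vectors.
    """
    if use_env_guidance is None:
        use_env_guidance = config.use_env_guidance
    B, T = images.shape[0], images.shape[1]
    H, W = images.shape[2], images.shape[3]
    frames = anp.reshape(images, (B * T, H, W, 3))
    env_flat = anp.reshape(env_vectors, (B * T, config.env_dim))

    _, hierarchy = embed_environment(params, env_flat, config)

    x = bb._patch_embed(params["backbone"], frames, config.patch_size)
    attention_maps = {"A_s": [], "A_t": []}
    guided_out = None
    stage_feats = []
    for l, stage in enumerate(params["backbone"]["stages"]):
        x = bb.forward_stage(stage, config, x)
        guided_out = attn.env_guided_attention(params["guided"][l], x, hierarchy[l],
                                               use_env_guidance=use_env_guidance)
        enhanced, a_t = attn.spatial_attention(params["spatial"][l], guided_out["output"])
        attention_maps["A_s"].append(guided_out["A_s"])
        attention_maps["A_t"].append(a_t)
        stage_feats.append(enhanced)
        x = enhanced

    final = stage_feats[-1]                                  # (BT, h, w, C)
    h_sp, w_sp, C = final.shape[1], final.shape[2], final.shape[3]
    tokens = anp.reshape(final, (B * T, h_sp * w_sp, C))
    z = F.linear(params["token_proj"], tokens)               # (BT, HW, d)
    z = anp.mean(z, axis=1)                                  # per-step pooling
    z = anp.reshape(z, (B, T, config.embed_dim))

    h_temporal, temporal_attn = attn.temporal_attention(params["temporal"], z,
                                                        config.n_heads)
    attention_maps["temporal"] = temporal_attn
    h_last = h_temporal[:, -1, :]                            # (B, d)

    pooled_final = F.global_avg_pool(final)                  # (BT, C)
    pooled_final = anp.reshape(pooled_final, (B, T, C))[:, -1, :]
    v_sem = F.linear(params["vis_sem"], pooled_final)        # high-level semantics

    logits = F.linear(params["cls_head"], anp.concatenate([h_last, v_sem], axis=-1))
    stage_probs = F.softmax(logits, axis=-1)

    aux_outputs = {}
    for s in config.aux_scales:
        feat = stage_feats[s]
        pooled = anp.reshape(F.global_avg_pool(feat),
                             (B, T, config.stage_channels[s]))[:, -1, :]
        aux_outputs[s] = F.softmax(F.linear(params["aux_heads"][str(s)], pooled), axis=-1)

    pooled_mod = anp.reshape(F.global_avg_pool(guided_out["modulated"]),
                             (B, T, C))[:, -1, :]
    z_vis = F.linear(params["z_vis_proj"], pooled_mod)
    top_env = anp.reshape(hierarchy[-1], (B, T, config.env_hidden))[:, -1, :]
    z_env = F.linear(params["z_env_proj"], top_env)

    spatial_map = None
    if config.use_spatial_head and "spatial_head" in params:
        hi_res = stage_feats[0]
        logits_map = F.conv2d_1x1(params["spatial_head"], hi_res)[..., 0]
        h0, w0 = logits_map.shape[1], logits_map.shape[2]
        spatial_map = anp.reshape(F.sigmoid(logits_map), (B, T, h0, w0))[:, -1]

    return ModelOutputs(stage_probs=stage_probs, spatial_map=spatial_map,
                        aux_outputs=aux_outputs, z_env=z_env, z_vis=z_vis,
                        attention_maps=attention_maps)


class DiseaseWarningModel:
    """Convenience wrapper tying a parameter tree to its configuration."""

    def __init__(self, config: ModelConfig, params: Optional[dict] = None):
        self.config = config
        self.params = init_params(config) if params is None else params

    def forward(self, images, env_vectors, use_env_guidance=None) -> ModelOutputs:
        return forward(self.params, self.config, images, env_vectors,
                       use_env_guidance=use_env_guidance)

    def forward_sequence(self, sequence) -> ModelOutputs:
        """Forward a single :class:`~greensentry.preprocess.SequenceSample`."""
        images = sequence.images[None]
        envs = sequence.env_vectors[None]
        return self.forward(images, envs)

    def n_parameters(self) -> int:
        vec, _ = flatten(self.params)
        return vec.size

    def save(self, path: str, extra: Optional[dict] = None) -> None:
        """Single-file checkpoint: flat weights + embedded config (+ metadata)."""
        vec, _ = flatten(self.params)
        meta = {"config": self.config.__dict__, "extra": extra or {}}
        meta["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in meta["config"].items()}
        np.savez(path, weights=vec, meta=json.dumps(meta))

    @classmethod
    def load(cls, path: str):
        with np.load(path if str(path).endswith(".npz") else f"{path}.npz",
                     allow_pickle=False) as ckpt:
            meta = json.loads(str(ckpt["meta"]))
            weights = ckpt["weights"]
        cfg_dict = meta["config"]
        for key in ("stage_channels", "stage_downsamples", "aux_scales",
                    "early_to_symptomatic_days"):
            if key in cfg_dict and isinstance(cfg_dict[key], list):
                cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        template = init_params(config)
        _, unflatten = flatten(template)
        model = cls(config, params=unflatten(weights))
        model.checkpoint_extra = meta.get("extra", {})
        return model
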