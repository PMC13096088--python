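"""Parameter initialization helpers (Xavier-uniform throughout)."""

from __future__ import annotations

import numpy as np


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    """Xavier/Glorot uniform sample with the given fan-in/out.

    ``shape`` defaults to ``(fan_in, fan_out)``.
    """
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


def linear_params(rng: np.random.Generator, d_in: int, d_out: int) -> dict:
    return {"W": xavier_uniform(rng, d_in, d_out), "b": np.zeros(d_out)}


def layer_norm_params(d: int) -> dict:
    return {"gamma": np.ones(d), "beta": np.zeros(d)}


def conv3x3_params(rng: np.random.Generator, c_in: int, c_out: int) -> dict:
    fan_in, fan_out = 9 * c_in, 9 * c_out
    return {
        "W": xavier_uniform(rng, fan_in, fan_out, shape=(3, 3, c_in, c_out)),
        "b": np.zeros(c_out),
    }


def attention_params(rng: np.random.Generator, d: int) -> dict:
    return {
        "q": linear_params(rng, d, d),
        "k": linear_params(rng, d, d),
        "v": linear_params(rng, d, d),
        "proj": linear_params(rng, d, d),
    }


def ffn_params(rng: np.random.Generator, d: int, hidden: int) -> dict:
    return {"fc1": linear_params(rng, d, hidden), "fc2": linear_params(rng, hidden, d)}


def transformer_block_params(rng: np.random.Generator, d: int, ffn_hidden: int) -> dict:
    return {
        "attn": attention_params(rng, d),
        "ffn": ffn_params(rng, d, ffn_hidden),
        "ln1": layer_norm_params(d),
        "ln2": layer_norm_params(d),
    }
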