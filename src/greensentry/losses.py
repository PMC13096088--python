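"""Four-term joint training objective.

``total = sup + lambda_early * early + lambda_align * align + lambda_ds * ds``
with cross-entropy main supervision (optionally plus a pixel BCE/Dice term),
an early-stage upweighted cross-entropy, a cosine alignment penalty between
environmental and visual embeddings, and deeply supervised auxiliary scales.
All terms are built from autograd-compatible ops so the joint loss is
differentiable end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from greensentry.synthdata import STAGE_INDEX


@dataclass
class LossConfig:
    lambda_early: float = 0.5
    lambda_align: float = 0.1
    lambda_ds: float = 0.3
    beta: float = 0.5                 # spatial BCE weight (value not published)
    gamma: float = 1.0                # early upweight increment (value not published)
    alpha_per_scale: dict = None      # defaults to uniform over supervised scales
    epsilon: float = 1e-8             # log clamp and alignment guard
    spatial_loss: str = "bce"         # "bce" or "dice"

    def __post_init__(self):
        if min(self.lambda_early, self.lambda_align, self.lambda_ds) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class LossBreakdown:
    total: float
    sup: float
    early: float
    align: float
    ds: float

    def as_dict(self) -> dict:
        return {"total": float(self.total), "sup": float(self.sup),
                "early": float(self.early), "align": float(self.align),
                "ds": float(self.ds)}


def _cross_entropy_rows(y_hat, y, epsilon):
    """Per-sample cross-entropy -sum_c y_c log y_hat_c with clamped log."""
    return -anp.sum(y * anp.log(anp.clip(y_hat, epsilon, 1.0)), axis=-1)


def _bce(p_hat, p, epsilon):
    p_hat = anp.clip(p_hat, epsilon, 1.0 - epsilon)
    return -anp.mean(p * anp.log(p_hat) + (1 - p) * anp.log(1 - p_hat))


def _dice(p_hat, p, epsilon):
    inter = anp.sum(p_hat * p)
    return 1.0 - (2 * inter + epsilon) / (anp.sum(p_hat) + anp.sum(p) + epsilon)


def supervised_loss(y_hat, y, p_hat=None, p=None, beta: float = 0.5,
                    epsilon: float = 1e-8, spatial_loss: str = "bce"):
    """Mean cross-entropy plus beta-weighted pixel loss when masks are given."""
    y_hat = anp.asarray(y_hat) if isinstance(y_hat, np.ndarray) else y_hat
    if y_hat.shape != np.shape(y):
        raise ValueError("y_hat and y must have matching shapes")
    loss = anp.mean(_cross_entropy_rows(y_hat, y, epsilon))
    if p_hat is not None and p is not None:
        pixel = _dice(p_hat, p, epsilon) if spatial_loss == "dice" else _bce(p_hat, p, epsilon)
        loss = loss + beta * pixel
    return loss


def early_weighted_loss(y_hat, y, stages, gamma: float = 1.0, epsilon: float = 1e-8):
    """Cross-entropy with per-sample weights ``1 + gamma * [stage == early]``."""
    for g in stages:
        if g not in STAGE_INDEX:
            raise ValueError(f"unknown stage label {g!r}")
    w = np.array([1.0 + gamma * (g == "early") for g in stages])
    ce = _cross_entropy_rows(y_hat, y, epsilon)
    return anp.mean(w * ce)


def alignment_loss(z_env, z_vis, epsilon: float = 1e-8):
    """Mean of ``1 - cos(z_env, z_vis)`` with an epsilon-guarded denominator."""
    if z_env.shape != z_vis.shape:
        raise ValueError("z_env and z_vis must have equal shapes")
    dot = anp.sum(z_env * z_vis, axis=-1)
    norms = (anp.sqrt(anp.sum(z_env ** 2, axis=-1)) *
             anp.sqrt(anp.sum(z_vis ** 2, axis=-1)))
    return anp.mean(1.0 - dot / (norms + epsilon))


def deep_supervision_loss(aux_outputs: dict, y, alpha_per_scale: dict = None,
                          epsilon: float = 1e-8):
    """Weighted sum of per-scale supervised losses over the supervised set."""
    if not aux_outputs:
        return 0.0
    if alpha_per_scale is None:
        alpha_per_scale = {s: 1.0 / len(aux_outputs) for s in aux_outputs}
    total = 0.0
    for scale, y_hat in aux_outputs.items():
        if scale not in alpha_per_scale:
            raise ValueError(f"missing alpha weight for supervised scale {scale}")
        total = total + alpha_per_scale[scale] * supervised_loss(y_hat, y,
                                                                 epsilon=epsilon)
    return total


def joint_loss(outputs, y, stages, config: LossConfig = None,
               p=None) -> LossBreakdown:
    """Compose the four terms for a batch of :class:`ModelOutputs`.

    ``y`` is the one-hot target matrix, ``stages`` the per-sample stage
    label strings, ``p`` an optional pixel mask batch matching
    ``outputs.spatial_map``.
    """
    if config is None:
        config = LossConfig()
    sup = supervised_loss(outputs.stage_probs, y, outputs.spatial_map, p,
                          beta=config.beta, epsilon=config.epsilon,
                          spatial_loss=config.spatial_loss)
    early = early_weighted_loss(outputs.stage_probs, y, stages,
                                gamma=config.gamma, epsilon=config.epsilon)
    align = alignment_loss(outputs.z_env, outputs.z_vis, epsilon=config.epsilon)
    ds = deep_supervision_loss(outputs.aux_outputs, y,
                               alpha_per_scale=config.alpha_per_scale,
                               epsilon=config.epsilon)
    total = (sup + config.lambda_early * early + config.lambda_align * align
             + config.lambda_ds * ds)
    return LossBreakdown(total=total, sup=sup, early=early, align=align, ds=ds)


def one_hot(stages, n_classes: int = 3) -> np.ndarray:
    """Stage label strings -> one-hot rows."""
    out = np.zeros((len(stages), n_classes))
    for i, g in enumerate(stages):
        out[i, STAGE_INDEX[g]] = 1.0
    return out
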