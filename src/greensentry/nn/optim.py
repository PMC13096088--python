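"""AdamW on flat parameter vectors, plus the cosine-annealing schedule."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Decoupled weight-decay Adam operating on a 1-D parameter vector."""

    def __init__(self, n_params: int, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def step(self, params: np.ndarray, grads: np.ndarray, lr: float | None = None) -> np.ndarray:
        """Return the updated parameter vector (inputs are not mutated)."""
        if lr is None:
            lr = self.lr
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grads
        self.v = self.beta2 * self.v + (1 - self.beta2) * grads ** 2
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        update = mhat / (np.sqrt(vhat) + self.eps)
        return params - lr * (update + self.weight_decay * params)


def cosine_annealing_lr(base_lr: float, epoch: int, total_epochs: int,
                        min_lr: float = 0.0) -> float:
    """Cosine decay from ``base_lr`` at epoch 0 to ``min_lr`` at the last epoch."""
    if total_epochs <= 1:
        return base_lr
    frac = epoch / (total_epochs - 1)
    return min_lr + 0.5 * (base_lr - min_lr) * (1 + np.cos(np.pi * frac))
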