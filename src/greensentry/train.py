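"""End-to-end training loop on the CPU autograd stack."""

from __future__ import annotations

import logging
import os
from dataclasses import replace

import numpy as np
import pandas as pd
from autograd import value_and_grad
from autograd.misc.flatten import flatten

from greensentry import evaluation, preprocess
from greensentry.config import AppConfig
from greensentry.losses import joint_loss, one_hot
from greensentry.model.network import DiseaseWarningModel, forward
from greensentry.nn.optim import AdamW, cosine_annealing_lr

log = logging.getLogger(__name__)


def prepare_training_data(dataset, app: AppConfig, train_event_ids):
    """Fit normalization on the training events only, align, and window."""
    train_ids = set(train_event_ids)
    stats_vectors = preprocess.aggregate_event_vectors(dataset, app.align, train_ids)
    align_cfg = replace(app.align, norm_stats=preprocess.fit_norm_stats(stats_vectors))
    samples = preprocess.align_dataset(dataset, align_cfg, event_ids=train_ids)
    train_seqs = preprocess.build_sequences(samples, app.train.T)
    return train_seqs, align_cfg


def _batch_arrays(sequences):
    images = np.stack([s.images for s in sequences])
    envs = np.stack([s.env_vectors for s in sequences])
    y = one_hot([s.label for s in sequences])
    stages = [s.label for s in sequences]
    return images, envs, y, stages


def _early_f1(model_cfg, params, sequences, use_env_guidance, batch_size=16):
    """Validation early-stage F1 for checkpoint selection (NaN when undefined)."""
    from greensentry.evaluation import early_stage_metrics
    from greensentry.synthdata import STAGES
    preds = []
    for i in range(0, len(sequences), batch_size):
        batch = sequences[i:i + batch_size]
        images = np.stack([s.images for s in batch])
        envs = np.stack([s.env_vectors for s in batch])
        out = forward(params, model_cfg, images, envs,
                      use_env_guidance=use_env_guidance)
        preds.extend(STAGES[int(np.argmax(p))] for p in np.asarray(out.stage_probs))
    _, _, f1 = early_stage_metrics(preds, [s.label for s in sequences])
    return f1


def train_model(dataset, app: AppConfig, train_event_ids,
                use_env_guidance: bool = True, out_dir: str = None,
                max_train_sequences: int = None, val_event_ids=None):
    """Train on the given events; returns (model, history DataFrame).

    ``max_train_sequences`` caps the per-epoch workload (random seeded
    subsample) so smoke tests stay within CPU budgets. When
    ``val_event_ids`` is given, the returned model carries the parameters
    of the epoch with the best validation early-F1 (final epoch when the
    metric is never defined).
    """
    train_seqs, align_cfg = prepare_training_data(dataset, app, train_event_ids)
    val_seqs = []
    if val_event_ids:
        val_samples = preprocess.align_dataset(
            dataset, align_cfg, event_ids=set(val_event_ids))
        val_seqs = preprocess.build_sequences(val_samples, app.train.T)
    if not train_seqs:
        raise ValueError("no training sequences for the given events")
    rng = np.random.default_rng(app.train.seed)
    if max_train_sequences is not None and len(train_seqs) > max_train_sequences:
        pick = rng.choice(len(train_seqs), size=max_train_sequences, replace=False)
        train_seqs = [train_seqs[i] for i in sorted(pick)]

    model_cfg = replace(app.model, use_env_guidance=use_env_guidance,
                        T=app.train.T, seed=app.train.seed)
    model = DiseaseWarningModel(model_cfg)
    flat, unflatten = flatten(model.params)
    opt = AdamW(flat.size, lr=app.train.lr, weight_decay=app.train.weight_decay)

    loss_cfg = app.loss

    def batch_loss(vec, images, envs, y, stages):
        params = unflatten(vec)
        out = forward(params, model_cfg, images, envs,
                      use_env_guidance=use_env_guidance)
        return joint_loss(out, y, stages, loss_cfg).total

    loss_grad = value_and_grad(batch_loss)

    history = []
    best_val_f1, best_flat, best_epoch = -np.inf, None, None
    n = len(train_seqs)
    bs = app.train.batch_size
    if app.train.balance_classes:
        # mild sqrt-inverse-frequency resampling: boosts minority stages
        # without flattening the class prior entirely
        counts = {}
        for s in train_seqs:
            counts[s.label] = counts.get(s.label, 0) + 1
        weights = np.array([1.0 / np.sqrt(counts[s.label]) for s in train_seqs])
        weights = weights / weights.sum()
    for epoch in range(app.train.epochs):
        lr = (cosine_annealing_lr(app.train.lr, epoch, app.train.epochs)
              if app.train.schedule == "cosine" else app.train.lr)
        if app.train.balance_classes:
            order = rng.choice(n, size=n, replace=True, p=weights)
        else:
            order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, bs):
            batch = [train_seqs[i] for i in order[start:start + bs]]
            images, envs, y, stages = _batch_arrays(batch)
            if app.train.augment:
                images = np.stack([
                    np.stack([preprocess.augment(fr, app.augment, rng) for fr in seq])
                    for seq in images])
            value, grads = loss_grad(flat, images, envs, y, stages)
            if not np.isfinite(value):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            flat = opt.step(flat, grads, lr=lr)
            epoch_losses.append(float(value))

        model.params = unflatten(flat)
        images, envs, y, stages = _batch_arrays(train_seqs[:min(n, bs)])
        monitor = joint_loss(model.forward(images, envs), y, stages, loss_cfg)
        row = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(epoch_losses)),
               **monitor.as_dict()}
        if val_seqs:
            f1 = _early_f1(model_cfg, model.params, val_seqs, use_env_guidance)
            row["val_early_f1"] = f1
            if np.isfinite(f1) and f1 > best_val_f1:
                best_val_f1, best_flat, best_epoch = f1, flat.copy(), epoch
        history.append(row)
        log.info("epoch %d: mean train loss %.4f", epoch, row["train_loss"])

    model.params = unflatten(flat)
    if val_seqs and best_flat is not None:
        model.params = unflatten(best_flat)
        model.best_epoch = best_epoch
        model.best_val_early_f1 = best_val_f1
    history_df = pd.DataFrame(history)
    # validation events participated in model selection: guard them too
    guarded = sorted(set(train_event_ids) | set(val_event_ids or []))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        history_df.to_csv(os.path.join(out_dir, "training_log.csv"), index=False)
        model.save(os.path.join(out_dir, "checkpoint.npz"),
                   extra={"train_event_ids": guarded,
                          "seed": app.train.seed,
                          "norm_mu": list(align_cfg.norm_stats.mu),
                          "norm_sigma": list(align_cfg.norm_stats.sigma)})
    model.align_config = align_cfg
    model.train_event_ids = guarded
    return model, history_df


def evaluate_fold(model, dataset, app: AppConfig, test_event_ids, out_dir=None):
    """Evaluate a trained model on held-out events (leakage-guarded)."""
    overlap = set(test_event_ids) & set(getattr(model, "train_event_ids", []))
    if overlap:
        raise ValueError(f"evaluation events overlap training events: {sorted(overlap)}")
    align_cfg = model.align_config
    samples = preprocess.align_dataset(dataset, align_cfg, event_ids=test_event_ids)
    sequences = preprocess.build_sequences(samples, model.config.T)
    events_by_id = {ev.event_id: ev for ev in dataset.events}
    return evaluation.evaluate_run(model, sequences, events_by_id, out_dir=out_dir,
                                   threshold=app.eval.threshold,
                                   k=app.eval.k_consecutive)
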