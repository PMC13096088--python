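"""Multimodal temporal alignment and preprocessing.

Pipeline per image frame: closed-window mean aggregation of the
environmental stream around the acquisition instant, exponential
smoothing of the per-frame aggregated sequence, z-score normalization
with statistics fitted on training data only, and minimal-perturbation
image augmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from greensentry import synthdata
from greensentry.synthdata import EnvSeries, SyntheticDataset

log = logging.getLogger(__name__)


class EmptyWindowError(ValueError):
    """Raised when an aggregation window contains no observations."""

    def __init__(self, tau, half_window):
        self.tau = tau
        super().__init__(f"no environmental observations within "
                         f"[{tau} - {half_window}, {tau} + {half_window}]")


@dataclass
class NormStats:
    """Per-variable (mu, sigma) fitted on the training split."""

    mu: np.ndarray
    sigma: np.ndarray


@dataclass
class AlignmentConfig:
    half_window: pd.Timedelta = field(default_factory=lambda: pd.Timedelta(minutes=30))
    smoothing_alpha: float = 0.2
    norm_stats: Optional[NormStats] = None

    def __post_init__(self):
        if isinstance(self.half_window, (int, float)):
            self.half_window = pd.Timedelta(minutes=self.half_window)
        if self.half_window <= pd.Timedelta(0):
            raise ValueError("half_window must be positive")
        if not (0.0 < self.smoothing_alpha <= 1.0):
            raise ValueError("smoothing_alpha must lie in (0, 1]")


@dataclass
class AugmentConfig:
    brightness_range: float = 0.10
    contrast_range: float = 0.10
    min_crop_area: float = 0.95
    seed: int = 0


@dataclass
class AlignedSample:
    """One image frame with its aligned environmental vector and label."""

    image: np.ndarray          # H x W x 3 float in [0, 1]
    env_vector: np.ndarray     # aggregated + smoothed + normalized 4-vector
    timestamp: pd.Timestamp
    stage: str
    event_id: str
    lesion_frac: float = 0.0
    mask: Optional[np.ndarray] = None
    raw_env: Optional[np.ndarray] = None  # aggregated+smoothed, pre-normalization


@dataclass
class SequenceSample:
    """T consecutive aligned frames from one event; the model input unit."""

    event_id: str
    samples: list
    label: str                 # stage of the final frame

    def __len__(self):
        return len(self.samples)

    @property
    def images(self) -> np.ndarray:
        return np.stack([s.image for s in self.samples])

    @property
    def env_vectors(self) -> np.ndarray:
        return np.stack([s.env_vector for s in self.samples])

    @property
    def timestamp(self) -> pd.Timestamp:
        return self.samples[-1].timestamp


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def aggregate_window(env: EnvSeries, tau, half_window) -> np.ndarray:
    """Mean of all observations with t in the closed window [tau-dt, tau+dt].

    Falls back to the nearest single observation within 2*dt when the
    window is empty; beyond that an :class:`EmptyWindowError` is raised.
    """
    if len(env) == 0:
        raise EmptyWindowError(tau, half_window)
    tau = pd.Timestamp(tau)
    if isinstance(half_window, (int, float)):
        half_window = pd.Timedelta(minutes=half_window)
    lo = env.timestamps.searchsorted(tau - half_window, side="left")
    hi = env.timestamps.searchsorted(tau + half_window, side="right")
    if hi > lo:
        return env.values[lo:hi].mean(axis=0)
    # nearest-observation fallback within 2*dt
    deltas = np.abs((env.timestamps - tau).to_numpy())
    j = int(np.argmin(deltas))
    if deltas[j] <= 2 * half_window.to_timedelta64():
        return env.values[j].copy()
    raise EmptyWindowError(tau, half_window)


def ewma_smooth(series: np.ndarray, alpha: float) -> np.ndarray:
    """Exponentially weighted smoothing along axis 0.

    ``s[0] = x[0]``, ``s[t] = alpha * x[t] + (1 - alpha) * s[t-1]``.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    out = np.empty_like(x)
    out[0] = x[0]
    for t in range(1, len(x)):
        out[t] = alpha * x[t] + (1.0 - alpha) * out[t - 1]
    return out


def fit_norm_stats(train_vectors) -> NormStats:
    """Population mean/sd per variable over the training aggregates."""
    arr = np.asarray(list(train_vectors), dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if len(arr) < 2:
        raise ValueError("need at least 2 samples to fit normalization stats")
    return NormStats(mu=arr.mean(axis=0), sigma=arr.std(axis=0))  # divide-by-N


def normalize(env_vector: np.ndarray, stats: NormStats) -> np.ndarray:
    """Z-score each variable; raises if any sigma is degenerate."""
    bad = np.flatnonzero(stats.sigma <= 0)
    if bad.size:
        names = [synthdata.ENV_COLUMNS[k] if k < len(synthdata.ENV_COLUMNS) else str(k)
                 for k in bad]
        raise ValueError(f"zero standard deviation for variable(s): {', '.join(names)}")
    return (np.asarray(env_vector, dtype=float) - stats.mu) / stats.sigma


def denormalize(env_vector: np.ndarray, stats: NormStats) -> np.ndarray:
    return np.asarray(env_vector, dtype=float) * stats.sigma + stats.mu


def sample_augment_params(config: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw one augmentation parameter set.

    Brightness/contrast factors are uniform in ``1 +/- range``; the crop
    retains a uniform fraction of the area in ``[min_crop_area, 1]``.
    """
    return {
        "brightness": rng.uniform(1.0 - config.brightness_range,
                                  1.0 + config.brightness_range),
        "contrast": rng.uniform(1.0 - config.contrast_range,
                                1.0 + config.contrast_range),
        "crop_area": rng.uniform(config.min_crop_area, 1.0),
    }


def augment(image: np.ndarray, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Minimal-perturbation augmentation.

    Applies a sampled brightness factor, a contrast factor about the image
    mean, and a random crop retaining at least ``min_crop_area`` of the
    area, resized back to input size. Output is clipped to [0, 1]. Labels
    and masks are never touched.
    """
    img = np.asarray(image, dtype=float)
    H, W = img.shape[:2]
    theta = sample_augment_params(config, rng)

    out = img * theta["brightness"]
    mean = out.mean()
    out = mean + (out - mean) * theta["contrast"]

    if theta["crop_area"] < 1.0:
        scale = np.sqrt(theta["crop_area"])
        ch, cw = max(1, round(H * scale)), max(1, round(W * scale))
        y0 = rng.integers(0, H - ch + 1)
        x0 = rng.integers(0, W - cw + 1)
        crop = out[y0:y0 + ch, x0:x0 + cw]
        # nearest-neighbour resize back to (H, W)
        yi = np.clip((np.arange(H) * ch / H).astype(int), 0, ch - 1)
        xi = np.clip((np.arange(W) * cw / W).astype(int), 0, cw - 1)
        out = crop[np.ix_(yi, xi)]

    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset-level pipeline
# ---------------------------------------------------------------------------

def align_dataset(dataset: SyntheticDataset, config: AlignmentConfig,
                  root_dir: Optional[str] = None, load_images: bool = True,
                  event_ids=None) -> list:
    """Aggregate -> smooth -> normalize, one AlignedSample per manifest row.

    Smoothing runs over each event's aggregated sequence in temporal
    order, so no information crosses event boundaries. ``config.norm_stats``
    must already be fitted (on training events only). ``event_ids``
    optionally restricts alignment to a subset of events.
    """
    if config.norm_stats is None:
        raise ValueError("config.norm_stats must be fitted before aligning")
    if root_dir is None:
        import os
        root_dir = os.path.dirname(dataset.image_dir)

    samples = []
    events = (dataset.events if event_ids is None
              else [ev for ev in dataset.events if ev.event_id in set(event_ids)])
    for ev in events:
        sub = dataset.manifest[dataset.manifest["event_id"] == ev.event_id]
        sub = sub.sort_values("timestamp")
        agg = []
        for ts in sub["timestamp"]:
            try:
                agg.append(aggregate_window(dataset.env, ts, config.half_window))
            except EmptyWindowError as exc:
                raise EmptyWindowError(ts, config.half_window) from exc
        smoothed = ewma_smooth(np.asarray(agg), config.smoothing_alpha)
        for (_, row), raw in zip(sub.iterrows(), smoothed):
            image = (synthdata.load_image(root_dir, row["frame_path"])
                     if load_images else None)
            samples.append(AlignedSample(
                image=image,
                env_vector=normalize(raw, config.norm_stats),
                timestamp=pd.Timestamp(row["timestamp"]),
                stage=row["stage"],
                event_id=row["event_id"],
                lesion_frac=float(row["lesion_frac"]),
                raw_env=raw,
            ))
    return samples


def aggregate_event_vectors(dataset: SyntheticDataset, config: AlignmentConfig,
                            event_ids) -> np.ndarray:
    """Aggregated+smoothed env vectors for the given events (for stats fitting)."""
    vecs = []
    for ev in dataset.events:
        if ev.event_id not in event_ids:
            continue
        sub = dataset.manifest[dataset.manifest["event_id"] == ev.event_id]
        sub = sub.sort_values("timestamp")
        agg = [aggregate_window(dataset.env, ts, config.half_window)
               for ts in sub["timestamp"]]
        vecs.append(ewma_smooth(np.asarray(agg), config.smoothing_alpha))
    return np.concatenate(vecs, axis=0)


def build_sequences(samples, T: int) -> list:
    """Stride-1 sliding windows of T frames, never crossing events.

    Sequence label = stage of the final frame. Events shorter than T are
    skipped with a warning.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    by_event = {}
    for s in samples:
        by_event.setdefault(s.event_id, []).append(s)
    sequences = []
    for event_id, group in by_event.items():
        group = sorted(group, key=lambda s: s.timestamp)
        if len(group) < T:
            log.warning("event %s has %d < T=%d frames; skipped", event_id, len(group), T)
            continue
        for i in range(len(group) - T + 1):
            window = group[i:i + T]
            sequences.append(SequenceSample(event_id=event_id, samples=window,
                                            label=window[-1].stage))
    return sequences
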