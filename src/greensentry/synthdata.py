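"""Synthetic greenhouse multimodal data generator.

Produces minute-resolution environmental streams (temperature, relative
humidity, vapor-pressure deficit, CO2), staggered per-plant disease
incidence events whose onset follows sustained high-humidity episodes
with a configurable lag, and procedurally rendered RGB frames whose
lesion coverage tracks the ground-truth stage timeline. The generated
structure mirrors real greenhouse monitoring: continuous sensing, a few
image acquisitions per day, early stages with sub-5% lesion coverage
that progress to symptomatic within one to three days.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

STAGES = ("healthy", "early", "symptomatic")
STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

ENV_COLUMNS = ("temp_c", "rh_pct", "vpd_kpa", "co2_ppm")

_MINUTES_PER_DAY = 1440


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the synthetic greenhouse simulation."""

    n_events: int = 20
    days_per_event: int = 10
    env_sample_interval: int = 1          # minutes
    images_per_day: int = 3
    image_size: int = 64
    risk_rh_threshold: float = 85.0       # % RH
    risk_lag_days: float = 2.0            # episode end -> visible onset
    early_max_lesion_frac: float = 0.05
    early_to_symptomatic_days: tuple = (1.0, 3.0)
    episode_prob: float = 0.75            # chance an event window gets a risk episode
    hazard_scale: float = 0.5             # per-hour-of-exposure hazard rate
    lag_noise_frac: float = 0.10          # multiplicative jitter on the lag
    temp_noise_sd: float = 0.8
    rh_noise_sd: float = 2.0
    co2_noise_sd: float = 15.0
    start: str = "2024-03-01"
    seed: int = 0

    def __post_init__(self):
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not (2 <= self.images_per_day <= 4):
            raise ValueError("images_per_day must be in [2, 4]")
        if not (0.0 < self.early_max_lesion_frac < 1.0):
            raise ValueError("early_max_lesion_frac must be in (0, 1)")
        lo, hi = self.early_to_symptomatic_days
        if not (1.0 <= lo <= hi <= 3.0):
            raise ValueError("early_to_symptomatic_days must lie within [1, 3]")
        if _MINUTES_PER_DAY % self.env_sample_interval != 0:
            raise ValueError("env_sample_interval must divide one day evenly")
        if self.days_per_event < self.risk_lag_days + 5:
            raise ValueError(
                "days_per_event must exceed risk_lag_days + 5 so that the "
                "early->symptomatic window fits inside the event")

    @property
    def total_days(self) -> int:
        return self.n_events * self.days_per_event


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EnvSeries:
    """Timestamped 4-channel environmental stream."""

    timestamps: pd.DatetimeIndex
    values: np.ndarray  # (N, 4): temp_c, rh_pct, vpd_kpa, co2_ppm

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        rh = self.values[:, 1]
        if np.any(rh < 0) or np.any(rh > 100):
            raise ValueError("RH must lie in [0, 100]")
        if np.any(self.values[:, 2] < 0):
            raise ValueError("VPD must be non-negative")
        if np.any(self.values[:, 3] <= 0):
            raise ValueError("CO2 must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(ENV_COLUMNS))
        df.insert(0, "timestamp", self.timestamps)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EnvSeries":
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        return cls(ts, df[list(ENV_COLUMNS)].to_numpy(dtype=float))


@dataclass
class DiseaseEvent:
    """Ground-truth trajectory of one monitored plant."""

    event_id: str
    onset_time: Optional[pd.Timestamp]        # None for never-diseased plants
    symptomatic_time: Optional[pd.Timestamp]
    frame_times: pd.DatetimeIndex
    stage_timeline: list                      # per-frame stage names
    lesion_fracs: np.ndarray

    @property
    def diseased(self) -> bool:
        return self.onset_time is not None

    def __post_init__(self):
        self.lesion_fracs = np.asarray(self.lesion_fracs, dtype=float)
        idx = [STAGE_INDEX[s] for s in self.stage_timeline]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"{self.event_id}: stages must be monotone non-decreasing")
        if len(self.frame_times) != len(self.stage_timeline) or len(self.frame_times) != len(self.lesion_fracs):
            raise ValueError(f"{self.event_id}: per-frame fields must have equal length")


@dataclass
class SyntheticDataset:
    """A generated dataset: events + shared env stream + image files on disk."""

    events: list
    env: EnvSeries
    image_dir: str
    manifest: pd.DataFrame  # event_id, frame_path, timestamp, stage, lesion_frac
    config: SimConfig = field(default=None)

    def event_by_id(self, event_id: str) -> DiseaseEvent:
        for ev in self.events:
            if ev.event_id == event_id:
                return ev
        raise KeyError(event_id)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_vpd(temperature, rh):
    """Vapor-pressure deficit (kPa) from air temperature (degC) and RH (%).

    Uses the Magnus/Tetens saturation curve
    ``e_s(T) = 0.6108 * exp(17.27 T / (T + 237.3))`` so that
    ``VPD = e_s(T) * (1 - RH/100)``.
    """
    t = np.asarray(temperature, dtype=float)
    r = np.asarray(rh, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("temperature and rh must be finite")
    if np.any(r < 0) or np.any(r > 100):
        raise ValueError("rh must lie in [0, 100]")
    if np.any(t < -10) or np.any(t > 60):
        raise ValueError("temperature out of supported range [-10, 60] degC")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    out = es * (1.0 - r / 100.0)
    if out.ndim == 0:
        return float(out)
    return out


def _risk_episode_slots(config: SimConfig, rng: np.random.Generator):
    """Decide, per event window, whether/where a high-RH episode occurs.

    Returns a list of (start_minute, duration_minutes) in global stream time.
    Episodes are placed early enough in the window that onset + the
    symptomatic transition still fall inside it.
    """
    slots = []
    latest = config.days_per_event - config.risk_lag_days - 4.0
    for i in range(config.n_events):
        if rng.random() >= config.episode_prob:
            continue
        day = rng.uniform(0.5, max(0.6, latest))
        start = (i * config.days_per_event + day) * _MINUTES_PER_DAY
        duration = rng.uniform(4.0, 8.0) * 60.0
        slots.append((start, duration))
    return slots


def simulate_env(config: SimConfig) -> EnvSeries:
    """Generate the shared greenhouse environmental stream.

    Diurnal sinusoidal temperature and CO2, RH anti-phase with temperature,
    plus injected multi-hour episodes above ``risk_rh_threshold``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.total_days * _MINUTES_PER_DAY // config.env_sample_interval
    start = pd.Timestamp(config.start)
    timestamps = pd.date_range(start, periods=n, freq=f"{config.env_sample_interval}min")
    minutes = np.arange(n, dtype=float) * config.env_sample_interval
    hod = (minutes / 60.0) % 24.0

    temp = 21.0 + 6.0 * np.sin(2 * np.pi * (hod - 9.0) / 24.0)
    temp = temp + rng.normal(0.0, config.temp_noise_sd, size=n)

    rh = 62.0 - 12.0 * np.sin(2 * np.pi * (hod - 9.0) / 24.0)
    rh = rh + rng.normal(0.0, config.rh_noise_sd, size=n)

    # injected sustained high-humidity risk episodes with a decaying
    # persistence tail (humid spells relax back to baseline over ~half a day)
    for start_min, dur_min in _risk_episode_slots(config, rng):
        mask = (minutes >= start_min) & (minutes < start_min + dur_min)
        lift = config.risk_rh_threshold + 5.0 + rng.normal(0.0, 1.0, size=int(mask.sum()))
        rh[mask] = np.maximum(rh[mask], lift)
        tail = minutes >= start_min + dur_min
        dt_days = (minutes[tail] - (start_min + dur_min)) / _MINUTES_PER_DAY
        lifted = rh[tail] + 22.0 * np.exp(-dt_days / 0.7)
        # the tail stays strictly below the risk threshold: elevated humidity
        # persists, but the sustained-risk episode itself has ended
        rh[tail] = np.minimum(lifted, config.risk_rh_threshold - 0.5)

    rh = np.clip(rh, 20.0, 100.0)
    temp = np.clip(temp, -5.0, 55.0)

    co2 = 750.0 + 180.0 * np.cos(2 * np.pi * (hod - 4.0) / 24.0)
    co2 = np.clip(co2 + rng.normal(0.0, config.co2_noise_sd, size=n), 50.0, None)

    vpd = compute_vpd(temp, rh)
    values = np.column_stack([temp, rh, vpd, co2])
    return EnvSeries(timestamps, values)


def _exposure_runs(above: np.ndarray, interval_min: int, min_hours: float = 2.0):
    """Contiguous runs of True lasting at least ``min_hours``.

    Returns a list of (start_idx, end_idx) half-open index pairs.
    """
    runs = []
    n = len(above)
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if (j - i) * interval_min >= min_hours * 60.0:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _frame_times_for_window(window_start: pd.Timestamp, days: int,
                            images_per_day: int, rng: np.random.Generator) -> pd.DatetimeIndex:
    """Acquisition instants: ``images_per_day`` draws per day in daylight hours."""
    times = []
    for d in range(days):
        hours = np.sort(rng.uniform(8.0, 17.0, size=images_per_day))
        for h in hours:
            times.append(window_start + pd.Timedelta(days=d) + pd.Timedelta(minutes=round(h * 60)))
    return pd.DatetimeIndex(times)


def simulate_events(env: EnvSeries, config: SimConfig) -> list:
    """Derive per-plant disease events from the environmental stream.

    Each event monitors one plant over a ``days_per_event`` window of the
    shared stream. The probability of disease is a hazard of cumulative
    exposure to RH above ``risk_rh_threshold`` (``1 - exp(-scale * hours)``);
    when disease occurs, visible onset lags the end of the first sustained
    high-RH run by ``risk_lag_days`` with multiplicative jitter, and the
    symptomatic transition follows within ``early_to_symptomatic_days``.
    """
    span_days = (env.timestamps[-1] - env.timestamps[0]) / pd.Timedelta(days=1)
    if span_days + 1e-9 < config.days_per_event:
        raise ValueError("env series shorter than one event window")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    t0 = env.timestamps[0]
    rh = env.values[:, 1]
    events = []
    for i in range(config.n_events):
        w_start = t0 + pd.Timedelta(days=i * config.days_per_event)
        w_end = w_start + pd.Timedelta(days=config.days_per_event)
        in_window = (env.timestamps >= w_start) & (env.timestamps < w_end)
        idx0 = int(np.argmax(in_window)) if in_window.any() else 0
        above = rh[in_window] > config.risk_rh_threshold
        runs = _exposure_runs(above, config.env_sample_interval)

        onset = symptomatic = None
        if runs:
            s, e = runs[0]
            exposure_h = (e - s) * config.env_sample_interval / 60.0
            p_disease = 1.0 - np.exp(-config.hazard_scale * exposure_h)
            u = rng.random()
            lag_jitter = float(np.clip(rng.normal(0.0, config.lag_noise_frac), -0.25, 0.25))
            if u < p_disease:
                episode_end = env.timestamps[idx0 + e - 1]
                lag = config.risk_lag_days * (1.0 + lag_jitter)
                onset = episode_end + pd.Timedelta(days=lag)
                lo, hi = config.early_to_symptomatic_days
                symptomatic = onset + pd.Timedelta(days=float(rng.uniform(lo, hi)))
        else:
            rng.random()  # keep the stream aligned across configurations
            rng.normal()

        frame_times = _frame_times_for_window(w_start, config.days_per_event,
                                              config.images_per_day, rng)
        stages, fracs = _stage_timeline(frame_times, onset, symptomatic, config)
        events.append(DiseaseEvent(
            event_id=f"event_{i:03d}",
            onset_time=onset,
            symptomatic_time=symptomatic,
            frame_times=frame_times,
            stage_timeline=stages,
            lesion_fracs=fracs,
        ))
    return events


def _stage_timeline(frame_times, onset, symptomatic, config: SimConfig):
    """Per-frame stage labels and lesion coverage for one event."""
    stages, fracs = [], []
    for t in frame_times:
        if onset is None or t < onset:
            stages.append("healthy")
            fracs.append(0.0)
        elif t < symptomatic:
            prog = (t - onset) / (symptomatic - onset)
            frac = config.early_max_lesion_frac * (0.2 + 0.75 * float(prog))
            stages.append("early")
            fracs.append(frac)
        else:
            days_since = (t - symptomatic) / pd.Timedelta(days=1)
            frac = min(0.35, config.early_max_lesion_frac * 1.5 + 0.08 * float(days_since))
            stages.append("symptomatic")
            fracs.append(frac)
    return stages, np.asarray(fracs)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_SOIL = np.array([0.42, 0.31, 0.20])
_LEAF = np.array([0.18, 0.46, 0.16])
_CHLOROTIC = np.array([0.55, 0.56, 0.18])   # early: subdued yellowing
_NECROTIC = np.array([0.30, 0.16, 0.08])    # symptomatic: dark necrosis


def _ellipse_mask(size, cy, cx, ry, rx):
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / max(ry, 1e-6)) ** 2 + ((xx - cx) / max(rx, 1e-6)) ** 2 <= 1.0


def render_frame(lesion_frac: float, stage: str, size: int, rng: np.random.Generator,
                 return_masks: bool = False):
    """Render one procedural leaf frame as an 8-bit RGB array.

    The lesion pixel fraction within the plant mask matches ``lesion_frac``
    within +/-0.01 absolute (binary search on blob radius). Early-stage
    lesions are low-contrast chlorotic; symptomatic lesions high-contrast
    necrotic.
    """
    if not (0.0 <= lesion_frac < 1.0):
        raise ValueError("lesion_frac must lie in [0, 1)")
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    if stage == "healthy" and lesion_frac > 0:
        raise ValueError("healthy frames cannot carry lesions")

    cy = size / 2 + rng.uniform(-2, 2)
    cx = size / 2 + rng.uniform(-2, 2)
    plant = _ellipse_mask(size, cy, cx, 0.40 * size, 0.34 * size)
    plant_px = int(plant.sum())

    img = np.empty((size, size, 3))
    img[:] = _SOIL
    img += rng.normal(0.0, 0.02, size=(size, size, 3))
    texture = rng.normal(0.0, 0.03, size=(size, size, 1))
    yy = np.arange(size)[:, None, None]
    veins = 0.015 * np.sin(yy / 2.5)
    img[plant] = (_LEAF + texture + veins)[plant]

    lesion = np.zeros((size, size), dtype=bool)
    target = int(round(lesion_frac * plant_px))
    if target > 0:
        n_blobs = 1 + int(lesion_frac * plant_px / 60)
        centers, shapes = [], []
        for _ in range(n_blobs):
            for _attempt in range(100):
                by = rng.uniform(cy - 0.3 * size, cy + 0.3 * size)
                bx = rng.uniform(cx - 0.25 * size, cx + 0.25 * size)
                if plant[int(np.clip(by, 0, size - 1)), int(np.clip(bx, 0, size - 1))]:
                    break
            centers.append((by, bx))
            shapes.append((rng.uniform(0.7, 1.3), rng.uniform(0.7, 1.3)))

        def count(scale):
            m = np.zeros((size, size), dtype=bool)
            for (by, bx), (ay, ax) in zip(centers, shapes):
                m |= _ellipse_mask(size, by, bx, scale * ay, scale * ax)
            return m & plant

        lo_s, hi_s = 0.0, float(size)
        for _ in range(50):
            mid = 0.5 * (lo_s + hi_s)
            if count(mid).sum() < target:
                lo_s = mid
            else:
                hi_s = mid
        lesion = count(hi_s)

        color = _CHLOROTIC if stage == "early" else _NECROTIC
        blend = 0.10 if stage == "early" else 0.85
        img[lesion] = (1 - blend) * img[lesion] + blend * color

    out = (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)
    if return_masks:
        return out, plant, lesion
    return out


# ---------------------------------------------------------------------------
# dataset assembly / IO
# ---------------------------------------------------------------------------

def generate_dataset(config: SimConfig, out_dir: str) -> SyntheticDataset:
    """Simulate env + events, render frames, and write everything under out_dir."""
    env = simulate_env(config)
    events = simulate_events(env, config)

    image_dir = os.path.join(out_dir, "images")
    os.makedirs(image_dir, exist_ok=True)

    rows = []
    for ei, ev in enumerate(events):
        for fi, (t, stage, frac) in enumerate(zip(ev.frame_times, ev.stage_timeline,
                                                  ev.lesion_fracs)):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303, ei, fi]))
            img = render_frame(float(frac), stage, config.image_size, rng)
            rel = os.path.join("images", f"{ev.event_id}_f{fi:03d}.png")
            path = os.path.join(out_dir, rel)
            try:
                Image.fromarray(img).save(path)
            except OSError as exc:
                raise OSError(f"failed to write frame {path}: {exc}") from exc
            rows.append({
                "event_id": ev.event_id,
                "frame_path": rel,
                "timestamp": t.isoformat(),
                "stage": stage,
                "lesion_frac": float(frac),
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    env.to_frame().assign(timestamp=lambda d: d["timestamp"].map(pd.Timestamp.isoformat)) \
        .to_csv(os.path.join(out_dir, "env.csv"), index=False)

    ev_rows = [{
        "event_id": ev.event_id,
        "diseased": ev.diseased,
        "onset_time": ev.onset_time.isoformat() if ev.diseased else "",
        "symptomatic_time": ev.symptomatic_time.isoformat() if ev.diseased else "",
    } for ev in events]
    pd.DataFrame(ev_rows).to_csv(os.path.join(out_dir, "events.csv"), index=False)

    return SyntheticDataset(events=events, env=env, image_dir=image_dir,
                            manifest=manifest, config=config)


def load_dataset(out_dir: str) -> SyntheticDataset:
    """Reload a dataset previously written by :func:`generate_dataset`."""
    env = EnvSeries.from_frame(pd.read_csv(os.path.join(out_dir, "env.csv")))
    manifest = pd.read_csv(os.path.join(out_dir, "manifest.csv"))
    ev_meta = pd.read_csv(os.path.join(out_dir, "events.csv"),
                          dtype={"onset_time": str, "symptomatic_time": str},
                          keep_default_na=False)
    events = []
    for _, row in ev_meta.iterrows():
        sub = manifest[manifest["event_id"] == row["event_id"]]
        diseased = str(row["diseased"]).lower() == "true"
        events.append(DiseaseEvent(
            event_id=row["event_id"],
            onset_time=pd.Timestamp(row["onset_time"]) if diseased else None,
            symptomatic_time=pd.Timestamp(row["symptomatic_time"]) if diseased else None,
            frame_times=pd.DatetimeIndex(pd.to_datetime(sub["timestamp"])),
            stage_timeline=list(sub["stage"]),
            lesion_fracs=sub["lesion_frac"].to_numpy(dtype=float),
        ))
    return SyntheticDataset(events=events, env=env,
                            image_dir=os.path.join(out_dir, "images"),
                            manifest=manifest, config=None)


def load_image(out_dir: str, rel_path: str) -> np.ndarray:
    """Decode a manifest frame to a float array in [0, 1]."""
    with Image.open(os.path.join(out_dir, rel_path)) as im:
        return np.asarray(im.convert("RGB"), dtype=float) / 255.0
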