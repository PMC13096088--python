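"""Early-warning evaluation suite.

Confusion-matrix metrics under a binary diseased-vs-healthy reduction,
one-vs-rest early-stage metrics, the lead-time metric with a
k-consecutive hysteresis detection rule, and leakage-free event-grouped
cross-validation splits.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from greensentry.synthdata import STAGES

UNDEFINED = float("nan")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class TrajectoryPrediction:
    """Per-event observation times, disease probabilities, and reference onset."""

    event_id: str
    times: pd.DatetimeIndex
    disease_probs: np.ndarray    # 1 - P(healthy) per observation
    t_ref: Optional[pd.Timestamp]

    def __post_init__(self):
        self.disease_probs = np.asarray(self.disease_probs, dtype=float)
        if np.any(self.disease_probs < 0) or np.any(self.disease_probs > 1):
            raise ValueError("disease probabilities must lie in [0, 1]")
        if len(self.times) != len(self.disease_probs):
            raise ValueError("times and probabilities must have equal length")


@dataclass
class DetectionRecord:
    event_id: str
    t_det: Optional[pd.Timestamp]
    t_ref: Optional[pd.Timestamp]

    @property
    def lead_days(self) -> float:
        if self.t_det is None or self.t_ref is None:
            return UNDEFINED
        return (self.t_ref - self.t_det) / pd.Timedelta(days=1)


@dataclass
class SplitPlan:
    """event_id -> fold index in [0, K)."""

    assignments: dict
    k: int

    def fold_events(self, fold: int) -> list:
        return sorted(e for e, f in self.assignments.items() if f == fold)

    def train_events(self, fold: int) -> list:
        return sorted(e for e, f in self.assignments.items() if f != fold)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_metrics(counts: ConfusionCounts):
    """(accuracy, recall, precision, f1); undefined ratios come back as NaN."""
    if counts.n == 0:
        raise ValueError("no samples to evaluate")
    accuracy = (counts.tp + counts.tn) / counts.n
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else UNDEFINED
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else UNDEFINED
    if math.isnan(recall) or math.isnan(precision) or precision + recall == 0:
        f1 = UNDEFINED
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return accuracy, recall, precision, f1


def binary_confusion(pred_stages, true_stages) -> ConfusionCounts:
    """Reduce 3-class predictions to diseased (early|symptomatic) vs healthy."""
    c = ConfusionCounts()
    for p, t in zip(pred_stages, true_stages):
        pd_, td = p != "healthy", t != "healthy"
        if pd_ and td:
            c.tp += 1
        elif not pd_ and not td:
            c.tn += 1
        elif pd_ and not td:
            c.fp += 1
        else:
            c.fn += 1
    return c


def multiclass_confusion(pred_stages, true_stages) -> np.ndarray:
    """Full 3x3 confusion matrix, rows = true, cols = predicted."""
    m = np.zeros((len(STAGES), len(STAGES)), dtype=int)
    idx = {s: i for i, s in enumerate(STAGES)}
    for p, t in zip(pred_stages, true_stages):
        m[idx[t], idx[p]] += 1
    return m


def early_stage_metrics(pred_stages, true_stages):
    """One-vs-rest (precision, recall, f1) for the early class."""
    tp = sum(1 for p, t in zip(pred_stages, true_stages) if p == "early" and t == "early")
    fp = sum(1 for p, t in zip(pred_stages, true_stages) if p == "early" and t != "early")
    fn = sum(1 for p, t in zip(pred_stages, true_stages) if p != "early" and t == "early")
    precision = tp / (tp + fp) if tp + fp else UNDEFINED
    recall = tp / (tp + fn) if tp + fn else UNDEFINED
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = UNDEFINED
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


# ---------------------------------------------------------------------------
# hysteresis detection and lead time
# ---------------------------------------------------------------------------

def detection_time(traj: TrajectoryPrediction, threshold: float = 0.5,
                   k: int = 3) -> Optional[pd.Timestamp]:
    """Time of the k-th observation of the first run of >= k strictly
    above-threshold probabilities; None when no such run exists."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(traj.disease_probs) == 0:
        raise ValueError(f"empty trajectory for event {traj.event_id}")
    run = 0
    for i, p in enumerate(traj.disease_probs):
        run = run + 1 if p > threshold else 0
        if run == k:
            return traj.times[i]
    return None


def lead_time(trajectories, threshold: float = 0.5, k: int = 3):
    """Mean lead (days) over detected truly-diseased events.

    Lead is ``t_ref - t_det`` so positive values mean the warning preceded
    the reference onset. Returns (mean_lead_days, per-event DetectionRecords,
    n_detected); undetected events are excluded from the mean.
    """
    diseased = [t for t in trajectories if t.t_ref is not None]
    if not diseased:
        raise ValueError("lead time requires at least one diseased trajectory")
    records = []
    for traj in diseased:
        records.append(DetectionRecord(event_id=traj.event_id,
                                       t_det=detection_time(traj, threshold, k),
                                       t_ref=traj.t_ref))
    leads = [r.lead_days for r in records if r.t_det is not None]
    mean_lead = float(np.mean(leads)) if leads else UNDEFINED
    return mean_lead, records, len(leads)


# ---------------------------------------------------------------------------
# event-based cross validation
# ---------------------------------------------------------------------------

def event_based_split(events, k: int = 5, seed: int = 0) -> SplitPlan:
    """Shuffle events and deal them round-robin into K folds, stratified by
    diseased/healthy status so fold class balance differs by at most one
    event."""
    events = list(events)
    if len(events) < k:
        raise ValueError(f"need at least {k} events for {k}-fold split")
    rng = np.random.default_rng(seed)
    diseased = [e for e in events if e.diseased]
    healthy = [e for e in events if not e.diseased]
    assignments = {}
    fold = 0
    for group in (diseased, healthy):
        order = rng.permutation(len(group))
        for j in order:
            assignments[group[j].event_id] = fold % k
            fold += 1
    return SplitPlan(assignments=assignments, k=k)


# ---------------------------------------------------------------------------
# run-level evaluation
# ---------------------------------------------------------------------------

REPORT_KEYS = ("accuracy", "recall", "precision", "f1", "early_precision",
               "early_recall", "early_f1", "lead_time_days", "n_detected",
               "n_events")


def build_trajectories(sequences, probs, events_by_id) -> list:
    """Group per-sequence class probabilities into per-event trajectories.

    ``probs`` rows are (healthy, early, symptomatic) probabilities for the
    final frame of each sequence; the disease probability is 1 - P(healthy).
    """
    grouped = {}
    for seq, p in zip(sequences, probs):
        grouped.setdefault(seq.event_id, []).append((seq.timestamp, 1.0 - float(p[0])))
    trajectories = []
    for event_id, obs in grouped.items():
        obs.sort(key=lambda o: o[0])
        ev = events_by_id[event_id]
        trajectories.append(TrajectoryPrediction(
            event_id=event_id,
            times=pd.DatetimeIndex([t for t, _ in obs]),
            disease_probs=np.array([p for _, p in obs]),
            t_ref=ev.onset_time,
        ))
    return trajectories


def evaluate_predictions(sequences, probs, events_by_id, threshold: float = 0.5,
                         k: int = 3) -> dict:
    """Full metric report from per-sequence probabilities."""
    pred_stages = [STAGES[int(np.argmax(p))] for p in probs]
    true_stages = [s.label for s in sequences]
    counts = binary_confusion(pred_stages, true_stages)
    accuracy, recall, precision, f1 = confusion_metrics(counts)
    e_prec, e_rec, e_f1 = early_stage_metrics(pred_stages, true_stages)
    trajectories = build_trajectories(sequences, probs, events_by_id)
    diseased = [t for t in trajectories if t.t_ref is not None]
    if diseased:
        mean_lead, records, n_det = lead_time(trajectories, threshold, k)
    else:
        mean_lead, records, n_det = UNDEFINED, [], 0
    return {
        "accuracy": accuracy, "recall": recall, "precision": precision, "f1": f1,
        "early_precision": e_prec, "early_recall": e_rec, "early_f1": e_f1,
        "lead_time_days": mean_lead, "n_detected": n_det,
        "n_events": len(trajectories),
        "confusion_3class": multiclass_confusion(pred_stages, true_stages).tolist(),
        "records": records,
    }


def evaluate_run(model, sequences, events_by_id, out_dir: Optional[str] = None,
                 threshold: float = 0.5, k: int = 3, batch_size: int = 16) -> dict:
    """Run the model over held-out sequences and write the JSON/CSV report."""
    probs = []
    for i in range(0, len(sequences), batch_size):
        batch = sequences[i:i + batch_size]
        images = np.stack([s.images for s in batch])
        envs = np.stack([s.env_vectors for s in batch])
        out = model.forward(images, envs)
        probs.extend(np.asarray(out.stage_probs))
    report = evaluate_predictions(sequences, probs, events_by_id, threshold, k)
    records = report.pop("records")
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        rows = [{"event_id": r.event_id,
                 "t_det": r.t_det.isoformat() if r.t_det is not None else "",
                 "t_ref": r.t_ref.isoformat() if r.t_ref is not None else "",
                 "lead_days": r.lead_days} for r in records]
        pd.DataFrame(rows, columns=["event_id", "t_det", "t_ref", "lead_days"]) \
            .to_csv(os.path.join(out_dir, "trajectories.csv"), index=False)
    report["records"] = records
    return report
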