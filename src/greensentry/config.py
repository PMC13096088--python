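"""Global YAML configuration: sim/align/model/loss/train/eval sections.

Two built-in profiles: ``paper`` carries the published hyperparameters
(batch 16, lr 1e-4, weight decay 1e-4, d=256, 6 temporal blocks);
``desk`` is a reduced CPU-scale profile with identical structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from greensentry.losses import LossConfig
from greensentry.model.config import ModelConfig, desk_config, paper_config
from greensentry.preprocess import AlignmentConfig, AugmentConfig
from greensentry.synthdata import SimConfig


@dataclass
class TrainConfig:
    optimizer: str = "adamw"
    weight_decay: float = 1e-4
    lr: float = 1e-4
    schedule: str = "cosine"
    batch_size: int = 16
    epochs: int = 5
    seed: int = 0
    augment: bool = False
    balance_classes: bool = False   # inverse-frequency batch resampling
    T: int = 6

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EvalConfig:
    threshold: float = 0.5
    k_consecutive: int = 3
    folds: int = 5


@dataclass
class AppConfig:
    profile: str = "desk"
    sim: SimConfig = field(default_factory=SimConfig)
    align: AlignmentConfig = field(default_factory=AlignmentConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = None
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)


_DESK_TRAIN = dict(batch_size=8, epochs=3, lr=3e-3)
_PAPER_TRAIN = dict(batch_size=16, epochs=50, lr=1e-4)


def build_config(sections: dict = None, profile: str = "desk") -> AppConfig:
    """Assemble an AppConfig from (possibly partial) YAML sections."""
    sections = dict(sections or {})
    profile = sections.pop("profile", profile)
    if profile not in ("desk", "paper"):
        raise ValueError(f"unknown profile {profile!r}")

    def section(name):
        return dict(sections.get(name) or {})

    sim = SimConfig(**section("sim"))

    align_kw = section("align")
    if "half_window_minutes" in align_kw:
        align_kw["half_window"] = align_kw.pop("half_window_minutes")
    align = AlignmentConfig(**align_kw)

    augment = AugmentConfig(**section("augment"))

    model_kw = section("model")
    for key in ("stage_channels", "stage_downsamples", "aux_scales"):
        if key in model_kw:
            model_kw[key] = tuple(model_kw[key])
    model = desk_config(**model_kw) if profile == "desk" else paper_config(**model_kw)

    loss = LossConfig(**section("loss"))

    train_kw = dict(_DESK_TRAIN if profile == "desk" else _PAPER_TRAIN)
    train_kw.update(section("train"))
    train = TrainConfig(**train_kw)

    ev = EvalConfig(**section("eval"))
    return AppConfig(profile=profile, sim=sim, align=align, augment=augment,
                     model=model, loss=loss, train=train, eval=ev)


def load_config(path: str = None, profile: str = "desk") -> AppConfig:
    sections = {}
    if path is not None:
        with open(path) as fh:
            sections = yaml.safe_load(fh) or {}
    return build_config(sections, profile=profile)
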