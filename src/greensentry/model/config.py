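"""Model hyperparameter configuration and the two built-in profiles."""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class ModelConfig:
    image_size: int = 64
    patch_size: int = 4
    stage_channels: tuple = (96, 192, 384)
    stage_downsamples: tuple = (8, 16, 32)   # relative to the input image
    window_size: int = 4
    backbone_heads: int = 4
    env_dim: int = 4
    env_hidden: int = 32                     # sensor-branch embedding width
    embed_dim: int = 256                     # temporal embedding d
    n_heads: int = 8
    n_temporal_blocks: int = 6
    ffn_mult: int = 4
    n_classes: int = 3
    T: int = 6
    aux_scales: tuple = (0, 1)               # backbone stages with auxiliary heads
    align_dim: int = 128                     # D for z_env / z_vis
    use_spatial_head: bool = False
    use_env_guidance: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.stage_channels) != len(self.stage_downsamples):
            raise ValueError("stage_channels and stage_downsamples must have equal length")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        for c in self.stage_channels:
            if c % self.backbone_heads != 0:
                raise ValueError("stage channels must be divisible by backbone_heads")
        if self.image_size % max(self.stage_downsamples) != 0:
            raise ValueError(
                f"image_size must be divisible by {max(self.stage_downsamples)}")
        if any(s >= len(self.stage_channels) for s in self.aux_scales):
            raise ValueError("aux_scales must index existing backbone stages")

    @property
    def n_stages(self) -> int:
        return len(self.stage_channels)

    def stage_resolution(self, stage: int) -> int:
        return self.image_size // self.stage_downsamples[stage]


def paper_config(**overrides) -> ModelConfig:
    """The configuration with the published dimensionality."""
    return replace(ModelConfig(), **overrides)


def desk_config(**overrides) -> ModelConfig:
    """A reduced-width profile for CPU-scale training; identical structure."""
    base = ModelConfig(
        stage_channels=(12, 24, 48),
        backbone_heads=4,
        env_hidden=16,
        embed_dim=32,
        n_heads=4,
        n_temporal_blocks=1,
        ffn_mult=2,
        align_dim=16,
        aux_scales=(1,),
    )
    return replace(base, **overrides)
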