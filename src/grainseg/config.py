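"""Configuration dataclasses and YAML round-trip.

The default configuration mirrors the published network at 640 x 640 input:
stage channels 96/192/384/768, a six-level 256-channel pyramid with detection
scales [12, 24, 48, 96, 192, 384] and aspect ratios [1, 1/2, 2], 32 prototype
masks, AdamW at lr 1e-4 with 500 warm-up iterations at 1e-5 and weight decay
5e-4.  ``Config.tiny()`` is a reduced preset (128 px input, narrow channels,
zero drop-path) used for deterministic desk-scale training and tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class BackboneConfig:
    embed_channels: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    patch_size: int = 4
    mlp_ratio: float = 4.0
    # None => each stage uses half its map side as the window, giving the
    # 4-window / 9-region partition; an int fixes the window in tokens.
    window_size: int | None = None
    drop_path: float = 0.2
    learnable_bias: bool = True

    def validate(self) -> None:
        if len(self.depths) != len(self.heads):
            raise ValueError("depths and heads must have equal length")
        for d in self.depths:
            if d % 2 != 0:
                raise ValueError(
                    "stage depths must be even: plain and shifted window "
                    f"attention alternate in pairs (got {self.depths})"
                )
        if self.patch_size != 4:
            raise ValueError("patch embedding is defined for patch_size 4")


@dataclass
class PyramidConfig:
    channels: int = 256
    upsample: str = "nearest"  # or "bilinear"
    scales: tuple[float, ...] = (12, 24, 48, 96, 192, 384)
    ratios: tuple[float, ...] = (1.0, 0.5, 2.0)


@dataclass
class HeadConfig:
    channels: int = 256
    num_classes: int = 8
    prototypes: int = 32
    fuse: bool = True  # cross-branch fusion (ablation switch)


@dataclass
class ProtoNetConfig:
    channels: int = 256
    upsample: str = "bilinear"
    enabled: bool = True  # ablation switch: False halves nothing, skips net


@dataclass
class LossConfig:
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    neg_pos_ratio: float = 3.0
    cls_weight: float = 1.0
    box_weight: float = 1.5
    mask_weight: float = 6.125
    variances: tuple[float, float] = (0.1, 0.2)


@dataclass
class RunConfig:
    input_side: int = 640
    batch_size: int = 8
    iterations: int = 80_000
    lr: float = 1e-4
    warmup_lr: float = 1e-5
    warmup_iters: int = 500
    weight_decay: float = 5e-4
    nms_iou: float = 0.5
    score_thr: float = 0.05
    mask_thr: float = 0.5
    top_n: int = 200
    max_dets: int = 100
    seed: int = 0
    tiny_mode: bool = False
    pixel_mean: tuple[float, float, float] = (0.485, 0.456, 0.406)
    pixel_std: tuple[float, float, float] = (0.229, 0.224, 0.225)

    def validate(self) -> None:
        if self.warmup_iters > self.iterations:
            raise ValueError("warmup_iters must not exceed iterations")


@dataclass
class Config:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    pyramid: PyramidConfig = field(default_factory=PyramidConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    protonet: ProtoNetConfig = field(default_factory=ProtoNetConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    run: RunConfig = field(default_factory=RunConfig)

    def validate(self) -> "Config":
        self.backbone.validate()
        self.run.validate()
        if self.run.tiny_mode and self.backbone.drop_path != 0.0:
            raise ValueError("tiny_mode requires drop_path 0 (determinism)")
        if self.run.input_side < 32:
            raise ValueError("input side below 32 px: stage-4 map would vanish")
        return self

    @classmethod
    def default(cls) -> "Config":
        return cls().validate()

    @classmethod
    def tiny(cls, seed: int = 0) -> "Config":
        """Desk-scale preset: 128 px input, narrow model, deterministic."""
        return cls(
            backbone=BackboneConfig(
                embed_channels=16, depths=(2, 2, 2, 2), heads=(1, 2, 4, 8),
                drop_path=0.0,
            ),
            pyramid=PyramidConfig(channels=32),
            head=HeadConfig(channels=32, prototypes=8),
            protonet=ProtoNetConfig(channels=32),
            run=RunConfig(
                input_side=128, batch_size=1, iterations=300, lr=2e-3,
                warmup_lr=2e-4, warmup_iters=10, seed=seed, tiny_mode=True,
            ),
        ).validate()

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        cfg = cls()
        for section_name, section_cls in (
            ("backbone", BackboneConfig), ("pyramid", PyramidConfig),
            ("head", HeadConfig), ("protonet", ProtoNetConfig),
            ("loss", LossConfig), ("run", RunConfig),
        ):
            if section_name in d:
                base = dataclasses.asdict(getattr(cfg, section_name))
                base.update(d[section_name] or {})
                # YAML gives lists; dataclass defaults use tuples
                for k, v in base.items():
                    if isinstance(v, list):
                        base[k] = tuple(v)
                setattr(cfg, section_name, section_cls(**base))
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "Config":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
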