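"""Six-level feature pyramid and anchor generation.

P4 is a 1x1 projection of C4; the top-down path upsamples by 2 and adds 1x1
lateral projections of C3, C2, C1 to produce P3, P2, P1 (each fused map then
passes a 3x3 smoothing convolution); P5 and P6 are successive stride-2 3x3
convolutions of P4.  All levels carry the same channel count (256 by
default); at 640-px input the spatial sides are 160, 80, 40, 20, 10, 5.

Each level detects at one scale — [12, 24, 48, 96, 192, 384] pixels for
P1..P6 — with three aspect ratios [1, 1/2, 2] per location.  "Scale" is the
square root of anchor area (w = scale * sqrt(ratio), h = scale / sqrt(ratio)),
so area is constant across ratios; anchor centres sit at pixel centres,
(col + 0.5, row + 0.5) * stride, in input-pixel coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from . import tensor as T
from .config import PyramidConfig
from .nn import Conv2d, Module
from .tensor import Tensor

LEVELS = ("P1", "P2", "P3", "P4", "P5", "P6")


class FeaturePyramid(Module):
    """Fuses backbone stage maps C1-C4 into pyramid levels P1-P6."""

    def __init__(self, in_channels: tuple[int, ...] = (96, 192, 384, 768),
                 cfg: PyramidConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg = cfg or PyramidConfig()
        rng = rng or np.random.default_rng(0)
        ch = cfg.channels
        self.lateral1 = Conv2d(in_channels[0], ch, 1, rng)
        self.lateral2 = Conv2d(in_channels[1], ch, 1, rng)
        self.lateral3 = Conv2d(in_channels[2], ch, 1, rng)
        self.project4 = Conv2d(in_channels[3], ch, 1, rng)
        self.smooth1 = Conv2d(ch, ch, 3, rng, padding=1)
        self.smooth2 = Conv2d(ch, ch, 3, rng, padding=1)
        self.smooth3 = Conv2d(ch, ch, 3, rng, padding=1)
        self.down5 = Conv2d(ch, ch, 3, rng, stride=2, padding=1)
        self.down6 = Conv2d(ch, ch, 3, rng, stride=2, padding=1)

    def forward(self, stages: dict[str, Tensor]) -> dict[str, Tensor]:
        c1, c2, c3, c4 = (stages[k] for k in ("C1", "C2", "C3", "C4"))
        batches = {c.shape[0] for c in (c1, c2, c3, c4)}
        if len(batches) > 1:
            raise ValueError(f"mismatched batch sizes across stage maps: {batches}")
        p4 = self.project4(c4)
        p3 = self.smooth3(T.upsample2x(p4, self.cfg.upsample) + self.lateral3(c3))
        p2 = self.smooth2(T.upsample2x(p3, self.cfg.upsample) + self.lateral2(c2))
        p1 = self.smooth1(T.upsample2x(p2, self.cfg.upsample) + self.lateral1(c1))
        p5 = self.down5(p4)
        p6 = self.down6(p5)
        return {"P1": p1, "P2": p2, "P3": p3, "P4": p4, "P5": p5, "P6": p6}


@dataclass(frozen=True)
class AnchorBox:
    """One prior box in input-pixel coordinates (centre-size form)."""

    cx: float
    cy: float
    w: float
    h: float
    level: int  # 1..6
    scale: float
    ratio: float


def generate_anchors(sides: list[int] | dict[str, int], input_side: int,
                     cfg: PyramidConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Tile anchors over every pyramid level.

    ``sides`` gives each level's spatial side (list P1..P6 or a level->side
    dict).  Returns ``(anchors, levels)``: anchors is (N, 4) float32 in
    centre-size form (cx, cy, w, h), levels is (N,) int8 with values 1..6.
    Ordering is level-major, then row-major over locations, with the three
    ratios fastest — matching the prediction head's output layout.
    """
    cfg = cfg or PyramidConfig()
    if isinstance(sides, dict):
        sides = [sides[k] for k in LEVELS[: len(sides)]]
    if len(sides) != len(cfg.scales):
        raise ValueError("one scale per pyramid level is required")
    boxes, levels = [], []
    for li, (side, scale) in enumerate(zip(sides, cfg.scales)):
        stride = input_side / side
        centres = (np.arange(side, dtype=np.float32) + 0.5) * stride
        cy, cx = np.meshgrid(centres, centres, indexing="ij")
        for_level = []
        for ratio in cfg.ratios:
            w = scale * math.sqrt(ratio)
            h = scale / math.sqrt(ratio)
            for_level.append(
                np.stack(
                    [cx, cy, np.full_like(cx, w), np.full_like(cx, h)], axis=-1
                )
            )
        lvl = np.stack(for_level, axis=2).reshape(-1, 4)  # ratios fastest
        boxes.append(lvl)
        levels.append(np.full(len(lvl), li + 1, dtype=np.int8))
    return (
        np.concatenate(boxes).astype(np.float32),
        np.concatenate(levels),
    )


def anchor_records(anchors: np.ndarray, levels: np.ndarray,
                   cfg: PyramidConfig | None = None) -> list[AnchorBox]:
    """Materialise (a possibly large) anchor array as AnchorBox records."""
    cfg = cfg or PyramidConfig()
    out = []
    for (cx, cy, w, h), lv in zip(anchors, levels):
        out.append(
            AnchorBox(float(cx), float(cy), float(w), float(h), int(lv),
                      float(cfg.scales[lv - 1]), float(w / h) if h else 0.0)
        )
    return out


def dump_anchors(anchors: np.ndarray, levels: np.ndarray, path,
                 cfg: PyramidConfig | None = None) -> None:
    """Write anchors to a JSON file for inspection."""
    recs = [asdict(a) for a in anchor_records(anchors, levels, cfg)]
    with open(path, "w") as f:
        json.dump(recs, f)


def pyramid_sides(input_side: int) -> list[int]:
    """Spatial sides of P1..P6 for a given input side (P1 = side/4, then
    halving with ceil)."""
    s = input_side // 4
    sides = [s]
    for _ in range(5):
        s = (s + 1) // 2
        sides.append(s)
    return sides
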