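"""Weight-shared prediction head with cross-branch fusion, and the
prototype-mask network.

The head runs the same weights over every pyramid level (so its parameter
count is independent of the number of levels).  A shared trunk of two 3x3
convolutions feeds three sibling branches predicting, per anchor, the class
scores (c+1 with background), the box regression 4-vector, and the k mask
coefficients.  The branches are chained: the class branch's pre-output
features are added into the box branch's input, and the box branch's
pre-output features into the coefficient branch's input, so each branch can
reuse what the previous one learned.  Coefficients pass through tanh so a
mask can subtract prototypes as well as add them.

The prototype network maps P1 through five convolutions with one 2x bilinear
upsampling in the middle — conv3x3 x2, upsample, conv3x3 x2, conv1x1 to k
channels — followed by ReLU, producing k non-negative image-sized prototype
masks at twice P1's resolution.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .config import HeadConfig, ProtoNetConfig
from .nn import Conv2d, Module
from .tensor import Tensor

ANCHORS_PER_LOC = 3


class PredictionHead(Module):
    """Parallel fused prediction head, applied identically at every level."""

    def __init__(self, cfg: HeadConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg = cfg or HeadConfig()
        rng = rng or np.random.default_rng(0)
        ch, a = cfg.channels, ANCHORS_PER_LOC
        self.trunk1 = Conv2d(ch, ch, 3, rng, padding=1)
        self.trunk2 = Conv2d(ch, ch, 3, rng, padding=1)
        self.cls_feat = Conv2d(ch, ch, 3, rng, padding=1)
        self.box_feat = Conv2d(ch, ch, 3, rng, padding=1)
        self.coef_feat = Conv2d(ch, ch, 3, rng, padding=1)
        self.cls_out = Conv2d(ch, a * (cfg.num_classes + 1), 3, rng, padding=1)
        self.box_out = Conv2d(ch, a * 4, 3, rng, padding=1)
        self.coef_out = Conv2d(ch, a * cfg.prototypes, 3, rng, padding=1)

    def forward(self, p: Tensor) -> dict[str, Tensor]:
        """p: one pyramid level (B, ch, H, W).

        Returns per-anchor predictions flattened in the anchor order of
        :func:`grainseg.pyramid.generate_anchors` (row-major locations,
        ratios fastest): class_logits (B, A, c+1), box_deltas (B, A, 4),
        coefficients (B, A, k) with values in (-1, 1).
        """
        cfg = self.cfg
        if p.shape[1] != cfg.channels:
            raise ValueError(
                f"head expects {cfg.channels}-channel input, got {p.shape[1]}"
            )
        t = T.relu(self.trunk1(p))
        t = T.relu(self.trunk2(t))
        f_cls = T.relu(self.cls_feat(t))
        cls = self.cls_out(f_cls)
        f_box = T.relu(self.box_feat(t + f_cls if cfg.fuse else t))
        box = self.box_out(f_box)
        f_coef = T.relu(self.coef_feat(t + f_box if cfg.fuse else t))
        coef = T.tanh(self.coef_out(f_coef))
        return {
            "class_logits": _to_anchor_major(cls, cfg.num_classes + 1),
            "box_deltas": _to_anchor_major(box, 4),
            "coefficients": _to_anchor_major(coef, cfg.prototypes),
        }

    def forward_levels(self, pyramid: dict[str, Tensor]) -> dict[str, Tensor]:
        """Apply the (shared) head to every level and concatenate anchors."""
        outs = [self(pyramid[k]) for k in sorted(pyramid, key=lambda s: int(s[1:]))]
        return {
            key: T.concat([o[key] for o in outs], axis=1)
            for key in ("class_logits", "box_deltas", "coefficients")
        }


def _to_anchor_major(x: Tensor, width: int) -> Tensor:
    """(B, 3*width, H, W) -> (B, H*W*3, width), ratios fastest."""
    B, C, H, W = x.shape
    a = C // width
    x = x.reshape(B, a, width, H, W)
    x = x.transpose(0, 3, 4, 1, 2)
    return x.reshape(B, H * W * a, width)


class ProtoNet(Module):
    """Five-convolution prototype-mask generator (output side = 2x input)."""

    def __init__(self, cfg: ProtoNetConfig | None = None, prototypes: int = 32,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg = cfg or ProtoNetConfig()
        rng = rng or np.random.default_rng(0)
        ch = cfg.channels
        self.conv1 = Conv2d(ch, ch, 3, rng, padding=1)
        self.conv2 = Conv2d(ch, ch, 3, rng, padding=1)
        self.conv3 = Conv2d(ch, ch, 3, rng, padding=1)
        self.conv4 = Conv2d(ch, ch, 3, rng, padding=1)
        self.proj = Conv2d(ch, prototypes, 1, rng)
        self.prototypes = prototypes

    def forward(self, p1: Tensor) -> Tensor:
        """p1: (B, ch, H, W) -> non-negative prototypes (B, k, 2H, 2W)."""
        x = T.relu(self.conv1(p1))
        x = T.relu(self.conv2(x))
        x = T.upsample2x(x, self.cfg.upsample)
        x = T.relu(self.conv3(x))
        x = T.relu(self.conv4(x))
        return T.relu(self.proj(x))
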