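"""End-to-end assembly of the one-stage segmenter.

Forward path: windowed-attention backbone -> C1..C4 -> six-level pyramid ->
weight-shared fused head (per-anchor class logits, box deltas, mask
coefficients over all 102,375 anchors at 640-px input) and prototype network
on P1.  Inference adds softmax scoring, box decoding, per-class Fast NMS,
linear mask assembly and crop/threshold finalisation.  Training adds anchor
matching and the three-part loss.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .assembly import assemble_masks, decode_boxes, detect, finalize
from .backbone import Backbone
from .config import Config
from .heads import PredictionHead, ProtoNet
from .losses import (
    box_loss,
    classification_loss,
    mask_loss,
    match_anchors,
    total_loss,
)
from .nn import Module
from .pyramid import FeaturePyramid, generate_anchors, pyramid_sides
from .tensor import Tensor

__all__ = ["GrainSegModel", "scene_to_record"]


def scene_to_record(scene) -> dict:
    """Convert a :class:`~grainseg.synthgrain.GrainScene` to the training
    record format ({"image", "instances": [{category_id, mask, bbox}]})."""
    return {
        "image_id": 0,
        "image": scene.image,
        "instances": [
            {
                "category_id": inst.class_id + 1,
                "mask": inst.mask,
                "bbox": list(inst.bbox),
                "area": inst.area,
            }
            for inst in scene.instances
        ],
    }


def _record_targets(record) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    insts = record["instances"]
    if not insts:
        return (
            np.zeros((0, 4), np.float32),
            np.zeros(0, np.int64),
            np.zeros((0,) + record["image"].shape[:2], bool),
        )
    boxes = np.array(
        [[b[0], b[1], b[0] + b[2], b[1] + b[3]] for b in (i["bbox"] for i in insts)],
        dtype=np.float32,
    )
    labels = np.array([i["category_id"] - 1 for i in insts], dtype=np.int64)
    masks = np.stack([np.asarray(i["mask"], bool) for i in insts])
    return boxes, labels, masks


class GrainSegModel(Module):
    """Backbone + pyramid + heads with loss and predict entry points."""

    def __init__(self, cfg: Config | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg = (cfg or Config.default()).validate()
        if cfg.head.channels != cfg.pyramid.channels:
            raise ValueError("head channels must match pyramid channels")
        rng = rng or np.random.default_rng(cfg.run.seed)
        side = cfg.run.input_side
        self.backbone = Backbone(cfg.backbone, side, rng)
        self.fpn = FeaturePyramid(tuple(self.backbone.stage_dims), cfg.pyramid, rng)
        self.head = PredictionHead(cfg.head, rng)
        self.protonet = ProtoNet(cfg.protonet, cfg.head.prototypes, rng)
        self.anchors, self.anchor_levels = generate_anchors(
            pyramid_sides(side), side, cfg.pyramid
        )

    # -- plumbing ------------------------------------------------------------
    def normalize(self, images: np.ndarray) -> np.ndarray:
        """uint8 (B, H, W, 3) or (H, W, 3) -> normalised float32 (B, 3, H, W)."""
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        x = images.astype(np.float32) / 255.0
        mean = np.asarray(self.cfg.run.pixel_mean, np.float32)
        std = np.asarray(self.cfg.run.pixel_std, np.float32)
        return ((x - mean) / std).transpose(0, 3, 1, 2)

    def forward(self, x) -> dict[str, Tensor]:
        stages = self.backbone(x)
        pyramid = self.fpn(stages)
        out = self.head.forward_levels(pyramid)
        out["prototypes"] = self.protonet(pyramid["P1"])
        return out

    # -- training ------------------------------------------------------------
    def loss(self, records: list[dict]) -> tuple[Tensor, dict[str, float]]:
        """Mean three-part loss over a batch of same-size training records."""
        cfg = self.cfg
        x = self.normalize(np.stack([r["image"] for r in records]))
        out = self.forward(x)
        n = len(records)
        cls_t = Tensor(0.0)
        box_t = Tensor(0.0)
        mask_t = Tensor(0.0)
        for i, rec in enumerate(records):
            gt_boxes, gt_labels, gt_masks = _record_targets(rec)
            match = match_anchors(
                self.anchors, gt_boxes, gt_labels,
                cfg.loss.pos_iou, cfg.loss.neg_iou,
            )
            cls_t = cls_t + classification_loss(
                out["class_logits"][i], match, cfg.loss.neg_pos_ratio
            )
            box_t = box_t + box_loss(
                out["box_deltas"][i], match, self.anchors, gt_boxes,
                cfg.loss.variances,
            )
            if cfg.protonet.enabled and len(gt_boxes):
                mask_t = mask_t + mask_loss(
                    out["prototypes"][i], out["coefficients"][i], match,
                    gt_masks, gt_boxes,
                )
        cls_t = cls_t * (1.0 / n)
        box_t = box_t * (1.0 / n)
        mask_t = mask_t * (1.0 / n)
        total = total_loss(cls_t, box_t, mask_t, cfg.loss)
        parts = {
            "cls": float(cls_t.data),
            "box": float(box_t.data),
            "mask": float(mask_t.data),
            "total": float(total.data),
        }
        return total, parts

    # -- inference -----------------------------------------------------------
    def predict(self, image: np.ndarray) -> dict[str, np.ndarray]:
        """Full single-image inference; returns final binary masks, boxes
        (corner form), scores and 0-based class ids."""
        cfg = self.cfg
        H, W = image.shape[:2]
        with T.no_grad():
            out = self.forward(self.normalize(image))
            scores = T.softmax(out["class_logits"][0], axis=-1).data
            deltas = out["box_deltas"][0].data
            coefs = out["coefficients"][0].data
            protos = out["prototypes"][0].data  # (k, h, w)
        boxes = decode_boxes(deltas, self.anchors, cfg.loss.variances, (W, H))
        dets = detect(
            boxes, scores, coefs, cfg.run.nms_iou, cfg.run.score_thr,
            cfg.run.top_n, cfg.run.max_dets,
        )
        soft = assemble_masks(protos.transpose(1, 2, 0), dets["coefficients"])
        return finalize(
            soft, dets["boxes"], dets["scores"], dets["classes"], (W, H),
            cfg.run.score_thr, cfg.run.mask_thr,
        )
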