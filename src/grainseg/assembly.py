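"""Post-processing: box decoding, Fast NMS and linear mask assembly.

Fast NMS replaces the sequential suppress-and-rescan loop with one matrix
step: per class, candidates are sorted by descending confidence, the pairwise
IoU matrix X is triangularised (X_ij = 0 for i >= j), and a candidate j
survives iff its column maximum K_j = max_i X_ij stays at or below the IoU
threshold.  Because a candidate can be suppressed by a box that was itself
suppressed, the kept set is always a subset of what sequential NMS keeps.

Final masks are linear combinations of the prototype stack: M = sigma(P C^T)
with P the (h, w, k) prototypes and C the (n, k) surviving coefficients; each
instance mask is cropped to its (slightly expanded) predicted box, upsampled
to input resolution, then thresholded.  Cropping happens before thresholding
so prototype activity cannot leak between adjacent instances — which matters
for densely packed grains.

All functions here operate on plain NumPy arrays (inference-time only).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "box_iou",
    "decode_boxes",
    "encode_boxes",
    "fast_nms",
    "detect",
    "assemble_masks",
    "finalize",
]


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two (n, 4) / (m, 4) corner-form [x1, y1, x2, y2] sets."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def decode_boxes(deltas: np.ndarray, anchors: np.ndarray,
                 variances: tuple[float, float] = (0.1, 0.2),
                 canvas: tuple[int, int] | None = None) -> np.ndarray:
    """Centre-size decoding of regression deltas against anchors.

    anchors are (N, 4) centre-size (cx, cy, w, h); returns corner-form
    (N, 4) [x1, y1, x2, y2], clipped to ``canvas`` = (width, height) if given.
    """
    deltas, anchors = np.asarray(deltas), np.asarray(anchors)
    if deltas.shape != anchors.shape:
        raise ValueError(f"shape mismatch: {deltas.shape} vs {anchors.shape}")
    v0, v1 = variances
    cx = anchors[:, 0] + deltas[:, 0] * v0 * anchors[:, 2]
    cy = anchors[:, 1] + deltas[:, 1] * v0 * anchors[:, 3]
    w = anchors[:, 2] * np.exp(deltas[:, 2] * v1)
    h = anchors[:, 3] * np.exp(deltas[:, 3] * v1)
    boxes = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)
    if canvas is not None:
        boxes[:, 0::2] = boxes[:, 0::2].clip(0, canvas[0])
        boxes[:, 1::2] = boxes[:, 1::2].clip(0, canvas[1])
    return boxes.astype(np.float32)


def encode_boxes(boxes: np.ndarray, anchors: np.ndarray,
                 variances: tuple[float, float] = (0.1, 0.2)) -> np.ndarray:
    """Inverse of :func:`decode_boxes`; ``boxes`` are corner-form targets."""
    boxes, anchors = np.asarray(boxes), np.asarray(anchors)
    bw = np.maximum(boxes[:, 2] - boxes[:, 0], 1e-6)
    bh = np.maximum(boxes[:, 3] - boxes[:, 1], 1e-6)
    bcx = (boxes[:, 0] + boxes[:, 2]) / 2
    bcy = (boxes[:, 1] + boxes[:, 3]) / 2
    v0, v1 = variances
    dx = (bcx - anchors[:, 0]) / (v0 * anchors[:, 2])
    dy = (bcy - anchors[:, 1]) / (v0 * anchors[:, 3])
    dw = np.log(bw / anchors[:, 2]) / v1
    dh = np.log(bh / anchors[:, 3]) / v1
    return np.stack([dx, dy, dw, dh], axis=1).astype(np.float32)


def fast_nms(iou: np.ndarray, scores: np.ndarray, iou_thr: float = 0.5,
             top_n: int = 200) -> list[np.ndarray]:
    """Matrix-parallel NMS on per-class IoU matrices.

    ``iou``: (c, n, n) pairwise IoU per class, rows/columns ordered by the
    (strictly non-increasing) per-class ``scores`` (c, n); candidates beyond
    ``top_n`` are dropped up front.  Returns the kept column indices per
    class.  Raises if scores are not sorted descending (the matrix ordering
    contract would be violated).
    """
    iou = np.asarray(iou, dtype=np.float64)
    scores = np.atleast_2d(np.asarray(scores))
    if iou.ndim == 2:
        iou = iou[None]
    if np.any(scores[:, 1:] > scores[:, :-1] + 1e-9):
        raise ValueError("scores must be sorted in descending order per class")
    kept: list[np.ndarray] = []
    for k in range(iou.shape[0]):
        n = min(iou.shape[1], top_n)
        x = np.triu(iou[k, :n, :n], k=1)  # zero lower triangle and diagonal
        col_max = x.max(axis=0) if n else np.zeros(0)
        kept.append(np.flatnonzero(col_max <= iou_thr))
    return kept


def detect(boxes: np.ndarray, class_scores: np.ndarray, coefficients: np.ndarray,
           iou_thr: float = 0.5, score_thr: float = 0.05, top_n: int = 200,
           max_dets: int = 100) -> dict[str, np.ndarray]:
    """Full candidate filtering around :func:`fast_nms`.

    ``boxes`` (N, 4) corner form, ``class_scores`` (N, c+1) softmax scores
    with background in column 0, ``coefficients`` (N, k).  Per foreground
    class: threshold, take top_n by score (ties broken by lower candidate
    index), Fast NMS, then a global cap of ``max_dets`` detections.
    Returns arrays: boxes, scores, classes (0-based foreground ids),
    coefficients.
    """
    n_classes = class_scores.shape[1] - 1
    all_boxes, all_scores, all_cls, all_coef = [], [], [], []
    for c in range(n_classes):
        sc = class_scores[:, c + 1]
        cand = np.flatnonzero(sc > score_thr)
        if cand.size == 0:
            continue
        order = cand[np.lexsort((cand, -sc[cand]))][:top_n]
        iou = box_iou(boxes[order], boxes[order])
        keep = fast_nms(iou[None], sc[order][None], iou_thr, top_n)[0]
        sel = order[keep]
        all_boxes.append(boxes[sel])
        all_scores.append(sc[sel])
        all_cls.append(np.full(sel.size, c, dtype=np.int64))
        all_coef.append(coefficients[sel])
    if not all_boxes:
        k = coefficients.shape[1] if coefficients.ndim == 2 else 0
        return {
            "boxes": np.zeros((0, 4), np.float32),
            "scores": np.zeros(0, np.float32),
            "classes": np.zeros(0, np.int64),
            "coefficients": np.zeros((0, k), np.float32),
        }
    boxes_f = np.concatenate(all_boxes)
    scores_f = np.concatenate(all_scores)
    cls_f = np.concatenate(all_cls)
    coef_f = np.concatenate(all_coef)
    order = np.lexsort((np.arange(scores_f.size), -scores_f))[:max_dets]
    return {
        "boxes": boxes_f[order].astype(np.float32),
        "scores": scores_f[order].astype(np.float32),
        "classes": cls_f[order],
        "coefficients": coef_f[order].astype(np.float32),
    }


def assemble_masks(protos: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
    """Linear mask assembly: sigmoid(P C^T).

    ``protos``: (h, w, k) prototype stack; ``coefficients``: (n, k).
    Returns (h, w, n) soft masks with values strictly in (0, 1).
    """
    protos = np.asarray(protos, dtype=np.float32)
    coefficients = np.atleast_2d(np.asarray(coefficients, dtype=np.float32))
    if protos.shape[-1] != coefficients.shape[-1]:
        raise ValueError(
            f"prototype count {protos.shape[-1]} != coefficient length "
            f"{coefficients.shape[-1]}"
        )
    logits = protos @ coefficients.T
    out = np.empty_like(logits)
    np.negative(np.abs(logits), out=out)
    np.exp(out, out=out)
    pos = logits >= 0
    out[pos] = 1.0 / (1.0 + out[pos])
    out[~pos] = out[~pos] / (1.0 + out[~pos])
    return out


def finalize(masks: np.ndarray, boxes: np.ndarray, scores: np.ndarray,
             classes: np.ndarray, input_size: tuple[int, int],
             score_thr: float = 0.05, mask_thr: float = 0.5,
             box_expand: float = 0.05) -> dict[str, np.ndarray]:
    """Turn soft masks into final binary per-instance masks.

    Masks (h, w, n) are bilinearly upsampled to ``input_size`` = (W, H),
    zeroed outside their (expanded) predicted box, and thresholded at
    ``mask_thr``; instances scoring at or below ``score_thr`` are dropped.
    """
    keep = np.flatnonzero(scores > score_thr)
    W, H = input_size
    out_masks = np.zeros((keep.size, H, W), dtype=bool)
    for j, i in enumerate(keep):
        m = masks[:, :, i]
        zoom = (H / m.shape[0], W / m.shape[1])
        big = ndimage.zoom(m, zoom, order=1, grid_mode=True, mode="nearest")
        big = big[:H, :W]
        x1, y1, x2, y2 = boxes[i]
        bw, bh = x2 - x1, y2 - y1
        x1 = max(0, int(np.floor(x1 - box_expand * bw)))
        y1 = max(0, int(np.floor(y1 - box_expand * bh)))
        x2 = min(W, int(np.ceil(x2 + box_expand * bw)))
        y2 = min(H, int(np.ceil(y2 + box_expand * bh)))
        crop = np.zeros((H, W), dtype=np.float32)
        crop[y1:y2, x1:x2] = big[y1:y2, x1:x2]
        out_masks[j] = crop > mask_thr
    return {
        "masks": out_masks,
        "boxes": boxes[keep].astype(np.float32),
        "scores": scores[keep].astype(np.float32),
        "classes": np.asarray(classes)[keep],
    }
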