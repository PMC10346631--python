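"""Anchor matching and the training objective.

Classification uses softmax cross-entropy over c+1 classes (c foreground plus
background) with hard-negative mining: only the highest-loss background
anchors participate, capped at three negatives per positive (3:1).  Box
regression uses the piecewise smooth-L1 penalty on encoded deltas — quadratic
within one unit, linear beyond, so its gradient never exceeds 1 per
coordinate.  The mask objective is pixel-wise binary cross-entropy between
the assembled mask (prototypes combined with the anchor's predicted
coefficients) and the matched truth mask, restricted to the truth box and
normalised by its area.  The total is a weighted sum of the three parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .assembly import box_iou, encode_boxes
from .config import LossConfig
from .tensor import Tensor

__all__ = [
    "MatchResult",
    "match_anchors",
    "smooth_l1",
    "box_loss",
    "classification_loss",
    "mask_loss",
    "total_loss",
]


def smooth_l1(x):
    """Piecewise localisation penalty: 0.5 x^2 if |x| < 1, else |x| - 0.5.

    Continuous and once-differentiable at |x| = 1, where both branches give
    0.5.  Elementwise on arrays; returns a float for scalar input.
    """
    a = np.abs(np.asarray(x, dtype=np.float64))
    y = np.where(a < 1.0, 0.5 * a * a, a - 0.5)
    return float(y) if y.ndim == 0 else y


@dataclass
class MatchResult:
    """Anchor-to-truth assignment for one image.

    labels: (A,) int — 0 background, 1..c foreground class (1-based),
    -1 ignored (neither positive nor negative).
    matched: (A,) int — index of the matched truth, -1 if none.
    max_iou: (A,) float — best IoU of each anchor with any truth.
    """

    labels: np.ndarray
    matched: np.ndarray
    max_iou: np.ndarray

    @property
    def positives(self) -> np.ndarray:
        return np.flatnonzero(self.labels > 0)

    @property
    def negatives(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)


def match_anchors(anchors: np.ndarray, gt_boxes: np.ndarray,
                  gt_labels: np.ndarray, pos_thr: float = 0.5,
                  neg_thr: float = 0.4) -> MatchResult:
    """IoU-based anchor assignment.

    ``anchors``: (A, 4) centre-size; ``gt_boxes``: (G, 4) corner form;
    ``gt_labels``: (G,) 0-based foreground class ids.  An anchor is positive
    if its best IoU >= pos_thr, negative if < neg_thr, ignored otherwise.
    Every truth is additionally force-matched to its best anchor, so each
    truth has at least one positive.  An empty truth list yields all
    negatives.
    """
    A = len(anchors)
    if len(gt_boxes) == 0:
        return MatchResult(
            np.zeros(A, np.int64), np.full(A, -1, np.int64), np.zeros(A)
        )
    ac = np.asarray(anchors, dtype=np.float64)
    corners = np.stack(
        [ac[:, 0] - ac[:, 2] / 2, ac[:, 1] - ac[:, 3] / 2,
         ac[:, 0] + ac[:, 2] / 2, ac[:, 1] + ac[:, 3] / 2], axis=1
    )
    iou = box_iou(corners, np.asarray(gt_boxes, dtype=np.float64))  # (A, G)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(A), best_gt]
    labels = np.zeros(A, np.int64)
    matched = np.full(A, -1, np.int64)
    pos = best_iou >= pos_thr
    ign = (best_iou >= neg_thr) & ~pos
    labels[ign] = -1
    labels[pos] = np.asarray(gt_labels)[best_gt[pos]] + 1
    matched[pos] = best_gt[pos]
    # force-match: the best anchor of each truth is positive regardless
    best_anchor = iou.argmax(axis=0)
    for g, a in enumerate(best_anchor):
        labels[a] = int(gt_labels[g]) + 1
        matched[a] = g
    return MatchResult(labels, matched, best_iou)


def box_loss(pred_deltas, match: MatchResult, anchors: np.ndarray,
             gt_boxes: np.ndarray,
             variances: tuple[float, float] = (0.1, 0.2)) -> Tensor:
    """Smooth-L1 over the four encoded coordinates, summed per positive and
    averaged over the positive count; 0 when there are no positives."""
    pos = match.positives
    if pos.size == 0:
        return Tensor(0.0)
    targets = encode_boxes(
        np.asarray(gt_boxes)[match.matched[pos]], np.asarray(anchors)[pos],
        variances,
    )
    pred = T.as_tensor(pred_deltas)[pos]
    return T.smooth_l1(pred - targets).sum() * (1.0 / pos.size)


def classification_loss(logits, match: MatchResult,
                        neg_pos_ratio: float = 3.0) -> Tensor:
    """Softmax cross-entropy with 3:1 hard-negative mining.

    All positives participate; negatives are ranked by their (detached)
    background loss and at most ``neg_pos_ratio *  n_pos`` of the hardest
    join.  The result is averaged over participating anchors.
    """
    logits = T.as_tensor(logits)
    pos, neg = match.positives, match.negatives
    if pos.size == 0:
        return Tensor(0.0)
    n_neg = min(neg.size, int(neg_pos_ratio * pos.size))
    if n_neg > 0:
        z = logits.data[neg]
        zs = z - z.max(axis=1, keepdims=True)
        bg_loss = np.log(np.exp(zs).sum(axis=1)) - zs[:, 0]
        hardest = neg[np.lexsort((neg, -bg_loss))[:n_neg]]
        idx = np.concatenate([pos, hardest])
    else:
        idx = pos
    labels = match.labels[idx].clip(min=0)
    return T.softmax_cross_entropy(logits[idx], labels)


def mask_loss(protos, coefficients, match: MatchResult,
              gt_masks: np.ndarray, gt_boxes: np.ndarray,
              max_positives: int = 100) -> Tensor:
    """Per-pixel BCE between assembled and truth masks inside the truth box.

    ``protos``: (k, h, w) prototype stack for one image; ``coefficients``:
    (A, k) predicted coefficients; ``gt_masks``: (G, H, W) binary truths at
    input resolution.  Each positive anchor's mask is assembled as
    sigmoid(P . c), compared against its truth downsampled to prototype
    resolution, weighted to the truth box, normalised by box area, and
    averaged over positives.  Zero-area truth boxes are skipped.
    """
    pos = match.positives[:max_positives]
    if pos.size == 0:
        return Tensor(0.0)
    protos = T.as_tensor(protos)
    coefficients = T.as_tensor(coefficients)
    k, h, w = protos.shape
    G, H, W = np.asarray(gt_masks).shape
    gm = np.asarray(gt_masks).astype(np.float32)
    if H % h == 0 and W % w == 0:
        # area-average pooling: targets in [0, 1], mirror-symmetric
        small = gm.reshape(G, h, H // h, w, W // w).mean(axis=(2, 4))
    else:
        rows = np.minimum((np.arange(h) + 0.5) * H / h, H - 1).astype(int)
        cols = np.minimum((np.arange(w) + 0.5) * W / w, W - 1).astype(int)
        small = gm[:, rows][:, :, cols]
    targets, weights, keep = [], [], []
    for i, a in enumerate(pos):
        g = match.matched[a]
        x1, y1, x2, y2 = gt_boxes[g]
        if x2 <= x1 or y2 <= y1:
            warnings.warn(f"skipping zero-area truth box {g}", stacklevel=2)
            continue
        xs, ys = w / W, h / H
        c1, c2 = int(np.floor(x1 * xs)), int(np.ceil(x2 * xs))
        r1, r2 = int(np.floor(y1 * ys)), int(np.ceil(y2 * ys))
        wmat = np.zeros((h, w), np.float32)
        area = max(0, r2 - r1) * max(0, c2 - c1)
        if area == 0:
            warnings.warn(f"skipping zero-area truth box {g}", stacklevel=2)
            continue
        wmat[r1:r2, c1:c2] = 1.0 / area
        targets.append(small[g])
        weights.append(wmat)
        keep.append(i)
    if not keep:
        return Tensor(0.0)
    coef_pos = coefficients[pos[np.asarray(keep)]]  # (P, k)
    flat = protos.reshape(k, h * w).transpose(1, 0)  # (hw, k)
    logits = flat @ coef_pos.transpose(1, 0)  # (hw, P)
    tgt = np.stack(targets, axis=-1).reshape(h * w, -1)
    wgt = np.stack(weights, axis=-1).reshape(h * w, -1)
    return T.binary_cross_entropy_with_logits(logits, tgt, wgt) * (1.0 / len(keep))


def total_loss(cls_loss, box_loss_value, mask_loss_value,
               cfg: LossConfig | None = None) -> Tensor:
    """Weighted sum of the three components (defaults 1.0 / 1.5 / 6.125)."""
    cfg = cfg or LossConfig()
    return (
        T.as_tensor(cls_loss) * cfg.cls_weight
        + T.as_tensor(box_loss_value) * cfg.box_weight
        + T.as_tensor(mask_loss_value) * cfg.mask_weight
    )
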