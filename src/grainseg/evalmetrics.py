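"""COCO-protocol mask average precision.

Metrics: mAP (mean AP over IoU thresholds 0.50:0.05:0.95, averaged over
classes), AP50 and AP75 (single thresholds), and AP_S / AP_M / AP_L
restricted by truth pixel area — small < 32^2, medium [32^2, 96^2), large
>= 96^2.  Matching is greedy per image/class/threshold in descending score
order, each truth matched at most once; precision is 101-point interpolated.
For the banded metrics, truths outside the band are ignored (a detection may
match one, and is then itself ignored), and unmatched detections whose own
area falls outside the band are ignored rather than counted as false
positives — the COCO convention.  All metrics are reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalConfig", "mask_iou", "evaluate", "format_metrics"]

_REC_THRS = np.linspace(0.0, 1.0, 101)


@dataclass
class EvalConfig:
    iou_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))
    area_bands: dict = field(
        default_factory=lambda: {
            "all": (0.0, float("inf")),
            "small": (0.0, 32.0**2),
            "medium": (32.0**2, 96.0**2),
            "large": (96.0**2, float("inf")),
        }
    )
    max_dets: int = 100

    def __post_init__(self):
        thr = np.asarray(self.iou_thresholds)
        if np.any(np.diff(thr) <= 0):
            raise ValueError("iou_thresholds must be strictly increasing")


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∩ b| / |a ∪ b| of two binary masks on the same canvas (0 if both
    are empty)."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(a & b) / union)


def _masks_iou(dets: list[np.ndarray], gts: list[np.ndarray]) -> np.ndarray:
    out = np.zeros((len(dets), len(gts)))
    for i, d in enumerate(dets):
        for j, g in enumerate(gts):
            out[i, j] = mask_iou(d, g)
    return out


def evaluate(detections: list[dict], truths: list[dict],
             cfg: EvalConfig | None = None,
             categories: list[int] | None = None) -> dict[str, float]:
    """Compute the mask-AP metric record.

    ``detections``: [{"image_id", "category_id", "score", "mask"}].
    ``truths``: [{"image_id", "category_id", "mask"}].
    Masks are binary arrays on the image canvas.  ``categories`` declares
    the valid category ids (default: those present in the truths); a
    detection outside that set is an error.  Classes without truths do not
    enter the class means.  Returns a dict with keys mAP, AP50, AP75, AP_S,
    AP_M, AP_L, values in percent (NaN where a band holds no truth of any
    class).
    """
    cfg = cfg or EvalConfig()
    if categories is None:
        categories = sorted({t["category_id"] for t in truths})
    else:
        categories = sorted(categories)
    unknown = {d["category_id"] for d in detections} - set(categories)
    if unknown:
        raise ValueError(f"unknown category id(s) in detections: {sorted(unknown)}")
    image_ids = sorted(
        {t["image_id"] for t in truths} | {d["image_id"] for d in detections}
    )

    # cap detections per image (top max_dets by score, ties by input order)
    capped: list[dict] = []
    for img in image_ids:
        dets = [d for d in detections if d["image_id"] == img]
        order = np.lexsort(
            (np.arange(len(dets)), -np.array([d["score"] for d in dets]))
        )[: cfg.max_dets]
        capped.extend(dets[i] for i in order)

    thrs = np.asarray(cfg.iou_thresholds)
    n_thr = len(thrs)
    # ap[band][class index, threshold index] (NaN = undefined)
    ap = {b: np.full((len(categories), n_thr), np.nan) for b in cfg.area_bands}

    for ci, cat in enumerate(categories):
        per_image = []
        for img in image_ids:
            gt = [t for t in truths if t["image_id"] == img and t["category_id"] == cat]
            dt = [d for d in capped if d["image_id"] == img and d["category_id"] == cat]
            dt.sort(key=lambda d: -d["score"])
            gt_masks = [np.asarray(t["mask"], bool) for t in gt]
            dt_masks = [np.asarray(d["mask"], bool) for d in dt]
            per_image.append(
                {
                    "scores": np.array([d["score"] for d in dt]),
                    "iou": _masks_iou(dt_masks, gt_masks),
                    "gt_area": np.array(
                        [float(np.count_nonzero(m)) for m in gt_masks]
                    ),
                    "dt_area": np.array(
                        [float(np.count_nonzero(m)) for m in dt_masks]
                    ),
                }
            )
        for band, (lo, hi) in cfg.area_bands.items():
            for ti, thr in enumerate(thrs):
                a = _ap_single(per_image, thr, lo, hi)
                ap[band][ci, ti] = a

    def _mean(x: np.ndarray) -> float:
        valid = ~np.isnan(x)
        return float(x[valid].mean() * 100.0) if valid.any() else float("nan")

    t50 = int(np.argmin(np.abs(thrs - 0.5)))
    t75 = int(np.argmin(np.abs(thrs - 0.75)))
    return {
        "mAP": _mean(ap["all"]),
        "AP50": _mean(ap["all"][:, t50]),
        "AP75": _mean(ap["all"][:, t75]),
        "AP_S": _mean(ap["small"]),
        "AP_M": _mean(ap["medium"]),
        "AP_L": _mean(ap["large"]),
    }


def _ap_single(per_image: list[dict], thr: float, lo: float, hi: float) -> float:
    """AP for one class at one IoU threshold and one truth-area band.

    Returns NaN when the band contains no truth of this class.
    """
    scores, tps, ignored = [], [], []
    n_pos = 0
    for rec in per_image:
        gt_ignore = ~((rec["gt_area"] >= lo) & (rec["gt_area"] < hi))
        n_pos += int(np.count_nonzero(~gt_ignore))
        order = np.argsort(gt_ignore, kind="stable")  # real truths first
        n_dt, n_gt = rec["iou"].shape
        gt_matched = np.zeros(n_gt, bool)
        for di in range(n_dt):
            best_iou, best_g = thr, -1
            for g in order:
                if gt_matched[g]:
                    continue
                if best_g > -1 and not gt_ignore[best_g] and gt_ignore[g]:
                    break  # a real match can't be improved by an ignored one
                if rec["iou"][di, g] < best_iou:
                    continue
                best_iou, best_g = rec["iou"][di, g], g
            scores.append(rec["scores"][di])
            if best_g == -1:
                in_band = lo <= rec["dt_area"][di] < hi
                tps.append(False)
                ignored.append(not in_band)
            else:
                gt_matched[best_g] = True
                tps.append(True)
                ignored.append(bool(gt_ignore[best_g]))
    if n_pos == 0:
        return float("nan")
    if not scores:
        return 0.0
    scores = np.asarray(scores)
    tps = np.asarray(tps)
    ignored = np.asarray(ignored)
    order = np.lexsort((np.arange(scores.size), -scores))
    tps, ignored = tps[order], ignored[order]
    tps, fps = tps[~ignored], ~tps[~ignored]
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(fps)
    recall = tp_cum / n_pos
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # right-to-left maximum makes precision monotone, then sample 101 points
    for i in range(precision.size - 1, 0, -1):
        precision[i - 1] = max(precision[i - 1], precision[i])
    idx = np.searchsorted(recall, _REC_THRS, side="left")
    q = np.where(idx < precision.size, precision[np.minimum(idx, precision.size - 1)], 0.0)
    return float(q.mean())


def format_metrics(metrics: dict[str, float]) -> str:
    """Human-readable one-line-per-metric table."""
    lines = [f"{k:>6}: {v:6.2f} %" for k, v in metrics.items()]
    return "\n".join(lines)
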