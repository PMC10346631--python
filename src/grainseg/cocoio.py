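"""COCO-dialect annotation and results I/O.

Segmentations are stored as uncompressed run-length encodings (RLE) in the
COCO convention: column-major (Fortran) pixel order, counts alternating
background/foreground and starting with the background run.  Boxes are
[x, y, width, height] in pixels.  Category ids are 1-based in the JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "rle_encode",
    "rle_decode",
    "mask_to_bbox",
    "write_dataset",
    "load_dataset",
    "write_results",
]


def rle_encode(mask: np.ndarray) -> dict:
    """Binary (H, W) mask -> {"size": [H, W], "counts": [...]} (uncompressed)."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.flatten(order="F").astype(np.int8)
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:  # counts must start with a background run
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    """Inverse of :func:`rle_encode`."""
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in rle["counts"]:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


def mask_to_bbox(mask: np.ndarray) -> list[float]:
    """Tight [x, y, w, h] box of a binary mask (zeros for an empty mask)."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return [0.0, 0.0, 0.0, 0.0]
    x1, y1 = float(xs.min()), float(ys.min())
    return [x1, y1, float(xs.max()) + 1 - x1, float(ys.max()) + 1 - y1]


def write_dataset(scenes, out_dir, class_names: list[str] | None = None) -> Path:
    """Write scenes as PNG images plus a COCO annotation JSON.

    ``scenes`` is an iterable of :class:`grainseg.synthgrain.GrainScene`.
    Returns the annotation file path.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    images, annotations = [], []
    ann_id = 1
    n_classes = 0
    for img_id, scene in enumerate(scenes, start=1):
        fname = f"scene_{img_id:04d}.png"
        Image.fromarray(scene.image).save(img_dir / fname)
        h, w = scene.image.shape[:2]
        images.append(
            {"id": img_id, "file_name": fname, "width": w, "height": h}
        )
        for inst in scene.instances:
            n_classes = max(n_classes, inst.class_id + 1)
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": inst.class_id + 1,
                    "segmentation": rle_encode(inst.mask),
                    "bbox": [float(v) for v in inst.bbox],
                    "area": int(inst.area),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    if class_names is None:
        class_names = [f"class_{i + 1}" for i in range(n_classes)]
    categories = [
        {"id": i + 1, "name": name} for i, name in enumerate(class_names)
    ]
    ann = {"images": images, "annotations": annotations, "categories": categories}
    path = out_dir / "annotations.json"
    path.write_text(json.dumps(ann))
    return path


def load_dataset(ann_path) -> list[dict]:
    """Load a COCO annotation file written by :func:`write_dataset`.

    Returns one record per image: {"image_id", "image" (H, W, 3 uint8),
    "file_name", "instances": [{"category_id", "mask", "bbox", "area"}]}.
    """
    ann_path = Path(ann_path)
    data = json.loads(ann_path.read_text())
    img_dir = ann_path.parent / "images"
    by_image: dict[int, dict] = {}
    for im in data["images"]:
        arr = np.asarray(Image.open(img_dir / im["file_name"]).convert("RGB"))
        by_image[im["id"]] = {
            "image_id": im["id"],
            "file_name": im["file_name"],
            "image": arr,
            "instances": [],
        }
    for a in data["annotations"]:
        by_image[a["image_id"]]["instances"].append(
            {
                "category_id": a["category_id"],
                "mask": rle_decode(a["segmentation"]),
                "bbox": list(a["bbox"]),
                "area": a["area"],
            }
        )
    return [by_image[k] for k in sorted(by_image)]


def write_results(detections: list[dict], path) -> None:
    """Write detections as a COCO results JSON.

    Each detection carries image_id, category_id, score, bbox [x, y, w, h]
    and an RLE segmentation; binary "mask" entries are encoded on the fly.
    """
    out = []
    for d in detections:
        seg = d.get("segmentation")
        if seg is None:
            seg = rle_encode(d["mask"])
        bbox = d.get("bbox")
        if bbox is None:
            bbox = mask_to_bbox(d["mask"])
        out.append(
            {
                "image_id": int(d["image_id"]),
                "category_id": int(d["category_id"]),
                "score": float(d["score"]),
                "bbox": [float(v) for v in bbox],
                "segmentation": seg,
            }
        )
    Path(path).write_text(json.dumps(out))
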