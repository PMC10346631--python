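"""Training, evaluation and prediction loops.

The optimiser is AdamW (weight decay 5e-4); the schedule is a linear warm-up
from ``warmup_lr`` (1e-5 at paper scale) to ``lr`` (1e-4) over
``warmup_iters`` iterations (500 at paper scale), constant afterwards.  All
randomness — initialisation, batch sampling, augmentation — flows from the
single run seed, so two runs with the same config produce identical loss
curves when drop-path is off.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .config import Config
from .evalmetrics import EvalConfig, evaluate
from .model import GrainSegModel, _record_targets
from .nn import AdamW
from .synthgrain import augment

__all__ = [
    "learning_rate_at",
    "train",
    "split_records",
    "evaluate_model",
    "predict_records",
]


def learning_rate_at(iteration: int, cfg: Config) -> float:
    """Linear warm-up then constant."""
    run = cfg.run
    if run.warmup_iters > 0 and iteration < run.warmup_iters:
        frac = iteration / run.warmup_iters
        return run.warmup_lr + frac * (run.lr - run.warmup_lr)
    return run.lr


def split_records(records: list[dict], ratio: float = 0.9,
                  seed: int = 0) -> tuple[list[dict], list[dict]]:
    """Shuffled train/validation split (default 0.9:0.1)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = max(1, int(round(ratio * len(records))))
    return (
        [records[i] for i in order[:n_train]],
        [records[i] for i in order[n_train:]],
    )


def train(cfg: Config, records: list[dict],
          out_dir: str | Path | None = None,
          model: GrainSegModel | None = None,
          augment_prob: float = 0.0,
          log_every: int = 50,
          checkpoint_every: int | None = None,
          verbose: bool = False) -> tuple[GrainSegModel, dict[str, list[float]]]:
    """Run ``cfg.run.iterations`` optimisation steps over ``records``.

    Returns the model and the per-iteration history of total/component
    losses and learning rate.  Aborts with a diagnostic naming the offending
    component if any loss goes non-finite.
    """
    cfg.validate()
    if not records:
        raise ValueError("no training records")
    rng = np.random.default_rng(cfg.run.seed)
    if model is None:
        model = GrainSegModel(cfg, rng)
    model.train()
    opt = AdamW(model.parameters(), lr=cfg.run.lr,
                weight_decay=cfg.run.weight_decay)
    history: dict[str, list[float]] = {
        "total": [], "cls": [], "box": [], "mask": [], "lr": []
    }
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for it in range(cfg.run.iterations):
        idx = rng.integers(0, len(records), size=cfg.run.batch_size)
        batch = [records[i] for i in idx]
        if augment_prob > 0:
            batch = [_maybe_augment(r, rng, augment_prob) for r in batch]
        total, parts = model.loss(batch)
        for name in ("cls", "box", "mask", "total"):
            if not math.isfinite(parts[name]):
                raise RuntimeError(
                    f"non-finite loss at iteration {it}: component "
                    f"'{name}' = {parts[name]} (all parts: {parts})"
                )
        model.zero_grad()
        total.backward()
        opt.lr = learning_rate_at(it, cfg)
        opt.step()
        history["total"].append(parts["total"])
        history["cls"].append(parts["cls"])
        history["box"].append(parts["box"])
        history["mask"].append(parts["mask"])
        history["lr"].append(opt.lr)
        if verbose and (it % log_every == 0 or it == cfg.run.iterations - 1):
            print(
                f"iter {it:6d}  lr {opt.lr:.2e}  total {parts['total']:.4f}  "
                f"cls {parts['cls']:.4f}  box {parts['box']:.4f}  "
                f"mask {parts['mask']:.4f}"
            )
        if (
            out_dir is not None
            and checkpoint_every
            and (it + 1) % checkpoint_every == 0
        ):
            model.save(out_dir / f"checkpoint_{it + 1:06d}.npz")
    if out_dir is not None:
        model.save(out_dir / "checkpoint_final.npz")
    model.eval()
    return model, history


def _maybe_augment(record: dict, rng: np.random.Generator, p: float) -> dict:
    """Random mirror/flip on a training record (crop would change the input
    side, so it is reserved for offline dataset expansion)."""
    from .model import scene_to_record
    from .synthgrain import GrainScene, GrainInstance, GrainSceneSpec

    ops = [op for op in ("hmirror", "vflip") if rng.random() < p]
    if not ops:
        return record
    insts = [
        GrainInstance(i["category_id"] - 1, np.asarray(i["mask"], bool),
                      list(i["bbox"]), int(i.get("area", 0)), (0, 0, 0, 0, 0))
        for i in record["instances"]
    ]
    spec = GrainSceneSpec(canvas=record["image"].shape[:2])
    scene = GrainScene(record["image"], insts, spec)
    return scene_to_record(augment(scene, ops, rng))


def evaluate_model(model: GrainSegModel, records: list[dict],
                   eval_cfg: EvalConfig | None = None) -> dict[str, float]:
    """Run inference on every record and score against its annotations."""
    dets, gts = [], []
    for rec in records:
        img_id = rec.get("image_id", 0)
        for inst in rec["instances"]:
            gts.append(
                {
                    "image_id": img_id,
                    "category_id": inst["category_id"],
                    "mask": np.asarray(inst["mask"], bool),
                }
            )
        pred = model.predict(rec["image"])
        for m, s, c in zip(pred["masks"], pred["scores"], pred["classes"]):
            dets.append(
                {
                    "image_id": img_id,
                    "category_id": int(c) + 1,
                    "score": float(s),
                    "mask": m,
                }
            )
    categories = list(range(1, model.cfg.head.num_classes + 1))
    return evaluate(dets, gts, eval_cfg, categories=categories)


def predict_records(model: GrainSegModel, records: list[dict]) -> list[dict]:
    """COCO-style detection dicts for a list of image records."""
    out = []
    for rec in records:
        pred = model.predict(rec["image"])
        for m, s, c, b in zip(
            pred["masks"], pred["scores"], pred["classes"], pred["boxes"]
        ):
            out.append(
                {
                    "image_id": rec.get("image_id", 0),
                    "category_id": int(c) + 1,
                    "score": float(s),
                    "mask": m,
                    "bbox": [
                        float(b[0]), float(b[1]),
                        float(b[2] - b[0]), float(b[3] - b[1]),
                    ],
                }
            )
    return out
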