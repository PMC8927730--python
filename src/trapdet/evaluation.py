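"""Detection metrics: per-class AP, AP50/AP75, mean AP, and mean recall.

Matching is greedy one-to-one, highest score first, same class only; AP
uses 101-point interpolation of the precision envelope.  Two threshold
modes are provided for the summary AP: ``triple`` averages over IoU
thresholds {0.50, 0.75, 0.95} and ``coco`` over {0.50 .. 0.95 step 0.05}.
``m_recall`` is the mean over classes of the maximum recall reached at
IoU 0.5.  Classes with zero ground truths are excluded from all means.

Ground truth and results use COCO detection JSON ([x, y, w, h] boxes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .boxes import Box, LabeledBox, pairwise_iou, pairwise_soft_iou
from .detector import Detection

__all__ = [
    "EvalConfig",
    "EvalResult",
    "match_detections",
    "average_precision",
    "evaluate",
    "load_coco_ground_truth",
    "save_coco_ground_truth",
    "detections_to_coco",
    "detections_from_coco",
    "format_table",
]

TRIPLE_THRESHOLDS = (0.50, 0.75, 0.95)
COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class EvalConfig:
    mode: str = "triple"  # triple | coco
    overlap_measure: str = "iou"  # iou | soft_iou
    soft_iou_beta: float = 1.1
    soft_iou_clamp: float = 0.1

    @property
    def thresholds(self) -> tuple[float, ...]:
        if self.mode == "triple":
            return TRIPLE_THRESHOLDS
        if self.mode == "coco":
            return COCO_THRESHOLDS
        raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class EvalResult:
    per_class_ap: dict[float, dict[int, float]]
    ap50: float
    ap75: float
    ap_mean: float
    m_recall: float
    mode: str = "triple"

    def summary(self) -> dict[str, float]:
        return {
            "AP": self.ap_mean,
            "AP50": self.ap50,
            "AP75": self.ap75,
            "mRecall": self.m_recall,
        }


def _overlap_matrix(dets: Sequence[Detection], gts: Sequence[LabeledBox], config: EvalConfig) -> np.ndarray:
    db = [d.box for d in dets]
    gb = [g.box for g in gts]
    if config.overlap_measure == "soft_iou":
        return pairwise_soft_iou(db, gb, beta=config.soft_iou_beta, clamp_factor=config.soft_iou_clamp)
    return pairwise_iou(db, gb)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[LabeledBox],
    iou_threshold: float,
    config: EvalConfig = EvalConfig(),
) -> np.ndarray:
    """TP(1)/FP(0) flags per detection, in descending-score order.

    Greedy: the highest-scoring detection claims its best still-unmatched
    same-class ground truth whose overlap clears the threshold.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    dets = [dets[i] for i in order]
    flags = np.zeros(len(dets), dtype=np.int8)
    if len(gts) == 0:
        return flags
    ov = _overlap_matrix(dets, gts, config)
    taken = np.zeros(len(gts), dtype=bool)
    for i, d in enumerate(dets):
        best_j, best_ov = -1, iou_threshold
        for j, g in enumerate(gts):
            if taken[j] or g.class_id != d.class_id:
                continue
            if ov[i, j] >= best_ov and (best_j < 0 or ov[i, j] > ov[i, best_j]):
                best_j = j
        if best_j >= 0:
            taken[best_j] = True
            flags[i] = 1
    return flags


def average_precision(flags: np.ndarray, num_gt: int) -> float:
    """101-point interpolated AP from score-ordered TP/FP flags."""
    if num_gt == 0:
        return float("nan")
    if len(flags) == 0:
        return 0.0
    tp = np.cumsum(flags == 1)
    fp = np.cumsum(flags == 0)
    recall = tp / num_gt
    precision = tp / (tp + fp)
    # precision envelope: best precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    interp = np.zeros_like(RECALL_GRID)
    # epsilon guards against float noise in the 0.01-spaced grid
    idx = np.searchsorted(recall, RECALL_GRID - 1e-10, side="left")
    valid = idx < len(env)
    interp[valid] = env[idx[valid]]
    return float(interp.mean())


def evaluate(
    dets_by_image: Mapping,
    gts_by_image: Mapping,
    config: EvalConfig = EvalConfig(),
) -> EvalResult:
    """Corpus metrics over per-image detection and ground-truth lists.

    Detections for one class are pooled across images and ranked globally
    by score before greedy per-image matching.
    """
    image_ids = sorted(gts_by_image.keys())
    classes = sorted(
        {g.class_id for gs in gts_by_image.values() for g in gs}
    )
    per_class_ap: dict[float, dict[int, float]] = {}
    recalls: dict[int, float] = {}
    for thr in config.thresholds:
        per_class_ap[thr] = {}
        for cls in classes:
            flags_all, scores_all = [], []
            num_gt = 0
            for img in image_ids:
                gts = [g for g in gts_by_image[img] if g.class_id == cls]
                num_gt += len(gts)
                dets = sorted(
                    (d for d in dets_by_image.get(img, []) if d.class_id == cls),
                    key=lambda d: -d.score,
                )
                flags = match_detections(dets, gts, thr, config)
                flags_all.append(flags)
                scores_all.append(np.array([d.score for d in dets]))
            flags_cat = np.concatenate(flags_all) if flags_all else np.zeros(0, np.int8)
            scores_cat = np.concatenate(scores_all) if scores_all else np.zeros(0)
            order = np.argsort(-scores_cat, kind="stable")
            flags_cat = flags_cat[order]
            per_class_ap[thr][cls] = average_precision(flags_cat, num_gt)
            if abs(thr - 0.5) < 1e-9:
                recalls[cls] = (
                    float((flags_cat == 1).sum() / num_gt) if num_gt else float("nan")
                )
    def mean_over_classes(thr: float) -> float:
        vals = [v for v in per_class_ap[thr].values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else 0.0

    ap50 = mean_over_classes(0.50)
    ap75 = mean_over_classes(0.75) if any(abs(t - 0.75) < 1e-9 for t in config.thresholds) else float("nan")
    ap_mean = float(np.mean([mean_over_classes(t) for t in config.thresholds]))
    rec_vals = [v for v in recalls.values() if not np.isnan(v)]
    m_recall = float(np.mean(rec_vals)) if rec_vals else 0.0
    return EvalResult(per_class_ap, ap50, ap75, ap_mean, m_recall, config.mode)


# -- COCO-format I/O ---------------------------------------------------


def load_coco_ground_truth(path: str | Path) -> tuple[dict[int, list[LabeledBox]], dict[int, str]]:
    """Read a COCO detection ground-truth file into per-image box lists."""
    with open(path) as f:
        doc = json.load(f)
    gts: dict[int, list[LabeledBox]] = {img["id"]: [] for img in doc["images"]}
    for ann in doc["annotations"]:
        x, y, w, h = ann["bbox"]
        gts[ann["image_id"]].append(
            LabeledBox(Box.from_xywh(x, y, w, h), ann["category_id"])
        )
    categories = {c["id"]: c["name"] for c in doc["categories"]}
    return gts, categories


def save_coco_ground_truth(
    path: str | Path,
    gts_by_image: Mapping[int, Sequence[LabeledBox]],
    image_sizes: Mapping[int, tuple[int, int]],
    categories: Mapping[int, str],
) -> None:
    images = [
        {"id": i, "height": image_sizes[i][0], "width": image_sizes[i][1],
         "file_name": f"{i:06d}.png"}
        for i in sorted(gts_by_image)
    ]
    annotations = []
    aid = 1
    for i in sorted(gts_by_image):
        for g in gts_by_image[i]:
            x, y, w, h = g.box.to_xywh()
            annotations.append(
                {"id": aid, "image_id": i, "category_id": g.class_id,
                 "bbox": [x, y, w, h], "area": w * h, "iscrowd": 0}
            )
            aid += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": k, "name": v} for k, v in sorted(categories.items())],
    }
    with open(path, "w") as f:
        json.dump(doc, f)


def detections_to_coco(dets_by_image: Mapping[int, Sequence[Detection]]) -> list[dict]:
    out = []
    for img in sorted(dets_by_image):
        for d in dets_by_image[img]:
            x, y, w, h = d.box.to_xywh()
            out.append(
                {"image_id": img, "category_id": d.class_id,
                 "bbox": [x, y, w, h], "score": d.score}
            )
    return out


def detections_from_coco(results: Sequence[dict]) -> dict[int, list[Detection]]:
    out: dict[int, list[Detection]] = {}
    for r in results:
        x, y, w, h = r["bbox"]
        out.setdefault(r["image_id"], []).append(
            Detection(Box.from_xywh(x, y, w, h), r["category_id"], r["score"])
        )
    return out


def format_table(result: EvalResult, categories: Mapping[int, str] | None = None) -> str:
    """Human-readable per-class AP50 table plus the summary row."""
    lines = ["class                     AP50"]
    ap50 = result.per_class_ap.get(0.50, {})
    for cls in sorted(ap50):
        name = (categories or {}).get(cls, f"class_{cls}")
        lines.append(f"{name:<24} {100 * ap50[cls]:6.1f}")
    s = result.summary()
    lines.append(
        f"AP {100*s['AP']:.1f} | AP50 {100*s['AP50']:.1f} | "
        f"AP75 {100*s['AP75']:.1f} | mRecall {100*s['mRecall']:.1f}"
    )
    return "\n".join(lines)
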