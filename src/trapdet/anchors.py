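"""Anchor grids, box delta coding, and non-maximum suppression.

Anchors are laid out one set per pyramid level, centered on feature-cell
centers ``stride * (i + 0.5)`` in image coordinates, row-major over
``(row, col, ratio)``.  Anchors are generated unclipped; clipping to the
image is a separate explicit step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .backbone import FeaturePyramid
from .boxes import pairwise_iou, pairwise_soft_iou

__all__ = [
    "AnchorConfig",
    "generate_anchors",
    "encode_deltas",
    "decode_deltas",
    "clip_boxes",
    "nms",
]


@dataclass(frozen=True)
class AnchorConfig:
    """One anchor size per pyramid level, shared aspect ratios.

    ``size_per_stride`` sets the square-anchor side as a multiple of the
    level stride (default 4, i.e. sides 16..256 px over strides 4..64).
    """

    size_per_stride: float = 4.0
    ratios: tuple[float, ...] = (1.0,)

    def base_size(self, stride: int) -> float:
        return self.size_per_stride * stride


def generate_anchors(
    image_size: tuple[int, int],
    pyramid: FeaturePyramid,
    config: AnchorConfig = AnchorConfig(),
) -> list[np.ndarray]:
    """Per-level ``[H*W*R, 4]`` anchor arrays in image coordinates."""
    out = []
    for lv in pyramid.levels:
        s = lv.stride
        size = config.base_size(s)
        cy = (np.arange(lv.height) + 0.5) * s
        cx = (np.arange(lv.width) + 0.5) * s
        boxes = np.empty((lv.height, lv.width, len(config.ratios), 4), dtype=np.float64)
        for r_idx, r in enumerate(config.ratios):
            h = size * math.sqrt(r)
            w = size / math.sqrt(r)
            boxes[:, :, r_idx, 0] = cx[None, :] - w / 2
            boxes[:, :, r_idx, 1] = cy[:, None] - h / 2
            boxes[:, :, r_idx, 2] = cx[None, :] + w / 2
            boxes[:, :, r_idx, 3] = cy[:, None] + h / 2
        out.append(boxes.reshape(-1, 4))
    return out


_CLIP_LOG = math.log(1000.0 / 16.0)


def encode_deltas(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """(dx, dy, dw, dh) log-space regression targets of boxes w.r.t. anchors."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + 0.5 * aw
    acy = anchors[:, 1] + 0.5 * ah
    bw = boxes[:, 2] - boxes[:, 0]
    bh = boxes[:, 3] - boxes[:, 1]
    bcx = boxes[:, 0] + 0.5 * bw
    bcy = boxes[:, 1] + 0.5 * bh
    return np.stack(
        [(bcx - acx) / aw, (bcy - acy) / ah, np.log(bw / aw), np.log(bh / ah)],
        axis=1,
    )


def decode_deltas(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Invert :func:`encode_deltas`; dw/dh clamped for numerical safety."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + 0.5 * aw
    acy = anchors[:, 1] + 0.5 * ah
    dx, dy = deltas[:, 0], deltas[:, 1]
    dw = np.clip(deltas[:, 2], -_CLIP_LOG, _CLIP_LOG)
    dh = np.clip(deltas[:, 3], -_CLIP_LOG, _CLIP_LOG)
    cx = acx + dx * aw
    cy = acy + dy * ah
    w = aw * np.exp(dw)
    h = ah * np.exp(dh)
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def clip_boxes(boxes: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    h, w = image_size
    out = boxes.copy()
    out[:, 0::2] = np.clip(out[:, 0::2], 0.0, w)
    out[:, 1::2] = np.clip(out[:, 1::2], 0.0, h)
    return out


def nms(
    boxes: np.ndarray,
    scores: np.ndarray,
    threshold: float,
    overlap: str = "iou",
    beta: float = 1.1,
    clamp_factor: float = 0.1,
) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, score-sorted.

    ``overlap='soft_iou'`` uses the distance-penalized score for the
    suppression test, so near-duplicates whose centers diverge are
    penalized less (test-phase retention with ``beta`` > 1 keeps more
    off-center boxes than plain IoU at the same threshold).
    """
    if len(boxes) == 0:
        return np.zeros(0, dtype=np.int64)
    order = np.argsort(-scores, kind="stable")
    if overlap == "soft_iou":
        mat = pairwise_soft_iou(boxes, boxes, beta=beta, clamp_factor=clamp_factor)
    else:
        mat = pairwise_iou(boxes, boxes)
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        suppressed |= mat[i] > threshold
    return np.asarray(keep, dtype=np.int64)
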