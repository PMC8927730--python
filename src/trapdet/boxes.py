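"""Axis-aligned box geometry: IoU and the distance-penalized Soft-IoU.

Boxes are continuous, 0-based, corner convention: ``(x1, y1)`` is the
top-left corner, area is ``(x2 - x1) * (y2 - y1)`` with no ``+1`` (COCO-style
continuous geometry).

Soft-IoU (SI) augments plain IoU with a penalty on the distance between box
centers, so that two candidates with the same overlap but different center
alignment receive different scores::

    SI(A, B) = beta * (1 - E(A_c, B_c) / max(diag_A, diag_B)) * IoU(A, B)

where ``E`` is the Euclidean distance between centers and ``diag`` the box
diagonal.  ``beta`` is a phase factor: 0.9 during training (keeps only
well-centered candidates as positives) and 1.1 at test time (retains
slightly off-center duplicates as valid outputs).  For stability the result
is clamped to within ``clamp_factor`` (default 0.1) times the raw IoU on
either side, so SI never strays more than 10% from IoU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box",
    "LabeledBox",
    "SoftIoUConfig",
    "iou",
    "center_distance_ratio",
    "soft_iou",
    "pairwise_iou",
    "pairwise_soft_iou",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in continuous pixel coordinates."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        vals = (self.x1, self.y1, self.x2, self.y2)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite, got {vals}")
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(
                f"box must have positive width and height, got {vals}"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "Box":
        return cls(x, y, x + w, y + h)

    def to_xywh(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.width, self.height)


@dataclass(frozen=True)
class LabeledBox:
    """A ground-truth box with its category id (1-based; 0 is background)."""

    box: Box
    class_id: int

    def __post_init__(self) -> None:
        if self.class_id < 1:
            raise ValueError("class_id must be >= 1")


@dataclass(frozen=True)
class SoftIoUConfig:
    """Phase factors and clamp bound for Soft-IoU.

    ``beta_train`` shrinks assignment scores (harder to become a positive),
    ``beta_test`` inflates duplicate-removal scores (easier to survive NMS);
    ``clamp_factor`` bounds the relative deviation of SI from raw IoU.
    """

    beta_train: float = 0.9
    beta_test: float = 1.1
    clamp_factor: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.beta_train <= 1.0):
            raise ValueError("beta_train must lie in (0, 1]")
        if self.beta_test < 1.0:
            raise ValueError("beta_test must be >= 1")
        if not (0.0 <= self.clamp_factor < 1.0):
            raise ValueError("clamp_factor must lie in [0, 1)")

    def beta(self, phase: str) -> float:
        if phase == "train":
            return self.beta_train
        if phase == "test":
            return self.beta_test
        raise ValueError(f"unknown phase {phase!r}")


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def center_distance_ratio(a: Box, b: Box) -> float:
    """Euclidean center distance divided by the larger box diagonal."""
    (ax, ay), (bx, by) = a.center, b.center
    return math.hypot(ax - bx, ay - by) / max(a.diagonal, b.diagonal)


def soft_iou(
    a: Box,
    b: Box,
    beta: float = 0.9,
    clamp_factor: float = 0.1,
) -> float:
    """Distance-penalized, phase-scaled, clamped IoU.

    The raw score ``beta * (1 - center_distance_ratio) * iou`` is clipped
    into ``[(1 - clamp_factor) * iou, (1 + clamp_factor) * iou]``.  When the
    boxes do not overlap the result is exactly 0 for any ``beta``.
    """
    if beta <= 0.0:
        raise ValueError("beta must be positive")
    if not (0.0 <= clamp_factor < 1.0):
        raise ValueError("clamp_factor must lie in [0, 1)")
    j = iou(a, b)
    if j == 0.0:
        return 0.0
    raw = beta * (1.0 - center_distance_ratio(a, b)) * j
    lo = (1.0 - clamp_factor) * j
    hi = (1.0 + clamp_factor) * j
    return min(max(raw, lo), hi)


def _stack(boxes: Iterable[Box | Sequence[float]]) -> np.ndarray:
    rows = []
    for b in boxes:
        if not isinstance(b, Box):
            b = Box(*b)
        rows.append((b.x1, b.y1, b.x2, b.y2))
    if not rows:
        return np.zeros((0, 4), dtype=np.float64)
    return np.asarray(rows, dtype=np.float64)


def pairwise_iou(boxes_a: Sequence, boxes_b: Sequence) -> np.ndarray:
    """|A| x |B| matrix of plain IoU values.

    Accepts ``Box`` instances or ``(x1, y1, x2, y2)`` quadruples; empty
    inputs yield an empty matrix of the right shape.
    """
    a = _stack(boxes_a)
    b = _stack(boxes_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros((a.shape[0], b.shape[0]), dtype=np.float64)
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(
        a[:, None, 0], b[None, :, 0]
    )
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(
        a[:, None, 1], b[None, :, 1]
    )
    inter = np.clip(iw, 0.0, None) * np.clip(ih, 0.0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def pairwise_soft_iou(
    boxes_a: Sequence,
    boxes_b: Sequence,
    beta: float = 0.9,
    clamp_factor: float = 0.1,
) -> np.ndarray:
    """Vectorized Soft-IoU: entry (i, j) equals ``soft_iou(a_i, b_j)``."""
    if beta <= 0.0:
        raise ValueError("beta must be positive")
    a = _stack(boxes_a)
    b = _stack(boxes_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros((a.shape[0], b.shape[0]), dtype=np.float64)
    j = pairwise_iou(a, b)
    ca = 0.5 * (a[:, :2] + a[:, 2:])
    cb = 0.5 * (b[:, :2] + b[:, 2:])
    dist = np.hypot(
        ca[:, None, 0] - cb[None, :, 0], ca[:, None, 1] - cb[None, :, 1]
    )
    diag_a = np.hypot(a[:, 2] - a[:, 0], a[:, 3] - a[:, 1])
    diag_b = np.hypot(b[:, 2] - b[:, 0], b[:, 3] - b[:, 1])
    diag = np.maximum(diag_a[:, None], diag_b[None, :])
    raw = beta * (1.0 - dist / diag) * j
    out = np.clip(raw, (1.0 - clamp_factor) * j, (1.0 + clamp_factor) * j)
    out[j == 0.0] = 0.0
    return out
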