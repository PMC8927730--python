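"""Seeded generator of light-trap-like pest scenes with COCO annotations.

A light-trap capture is a bright board photographed from above, dotted
with many small, dark, often near-identical insects.  The generator
emulates the statistics that make such scenes hard for detectors:

* objects are tiny — the mean pest box covers ``relative_area`` (default
  1.58%) of a reference "general object" box, itself a configured fraction
  of the image;
* the scale spread across classes is wide — the largest class's mean box
  area is ``scale_spread`` (default 32) times the smallest's, classes
  log-spaced in between;
* layouts range from sparse to dense (``objects_per_image``);
* designated class pairs are near-duplicates, differing by a small epsilon
  in a single shape parameter (``similarity_pairs``).

Pests are rendered as striped, rotated ellipses with class-specific axis
ratio, color and stripe frequency on a bright, lightly textured board.
Annotations use the analytic tight bounding box of each rendered ellipse.
Everything is deterministic per seed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .boxes import Box, LabeledBox

__all__ = [
    "SceneSpec",
    "ClassStyle",
    "class_styles",
    "generate_scene",
    "generate_dataset",
    "degrade_mist",
]


@dataclass(frozen=True)
class SceneSpec:
    image_size: tuple[int, int] = (800, 1088)  # (height, width)
    num_classes: int = 8
    objects_per_image: tuple[int, int] = (3, 12)
    relative_area: float = 0.0158
    reference_box_fraction: float = 0.38  # "general object" box as image fraction
    scale_spread: float = 32.0
    similarity_pairs: tuple[tuple[int, int], ...] = ()
    similarity_epsilon: float = 0.15
    mist_sigma: float = 0.0
    background_level: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 1:
            raise ValueError("need at least one class")
        if self.scale_spread < 1.0:
            raise ValueError("scale_spread must be >= 1")
        if not (0.0 < self.relative_area < 1.0):
            raise ValueError("relative_area must lie in (0, 1)")
        lo, hi = self.objects_per_image
        if lo < 0 or hi < lo:
            raise ValueError("objects_per_image must be a valid range")
        for a, b in self.similarity_pairs:
            if not (1 <= a <= self.num_classes and 1 <= b <= self.num_classes):
                raise ValueError("similarity pair classes out of range")

    @property
    def reference_box_area(self) -> float:
        h, w = self.image_size
        return self.reference_box_fraction * h * w

    def class_mean_areas(self) -> np.ndarray:
        """Per-class mean box areas, log-spaced over ``scale_spread`` and
        normalized so the across-class mean hits the relative-area target."""
        k = self.num_classes
        factors = self.scale_spread ** (np.arange(k) / max(k - 1, 1))
        target_mean = self.relative_area * self.reference_box_area
        return factors * (target_mean / factors.mean())


@dataclass(frozen=True)
class ClassStyle:
    axis_ratio: float
    color: tuple[float, float, float]
    stripe_freq: float
    stripe_phase: float


def class_styles(spec: SceneSpec) -> list[ClassStyle]:
    """Deterministic per-class appearance; similarity pairs share all
    parameters except a small epsilon on the stripe frequency."""
    rng = np.random.default_rng(spec.seed + 7919)
    styles = []
    for _ in range(spec.num_classes):
        styles.append(
            ClassStyle(
                axis_ratio=float(rng.uniform(1.3, 3.0)),
                color=tuple(rng.uniform(0.08, 0.45, size=3)),
                stripe_freq=float(rng.uniform(2.0, 8.0)),
                stripe_phase=float(rng.uniform(0, 2 * math.pi)),
            )
        )
    for a, b in spec.similarity_pairs:
        sa = styles[a - 1]
        styles[b - 1] = ClassStyle(
            sa.axis_ratio, sa.color,
            sa.stripe_freq + spec.similarity_epsilon, sa.stripe_phase,
        )
    return styles


def _ellipse_extents(area: float, ratio: float, theta: float) -> tuple[float, float, float, float]:
    """Semi-axes and tight half-extents of a rotated ellipse whose tight
    bounding box has the given area."""
    # unit-scale semi-axes with the class ratio
    a0, b0 = math.sqrt(ratio), 1.0 / math.sqrt(ratio)
    ex0 = math.sqrt((a0 * math.cos(theta)) ** 2 + (b0 * math.sin(theta)) ** 2)
    ey0 = math.sqrt((a0 * math.sin(theta)) ** 2 + (b0 * math.cos(theta)) ** 2)
    scale = math.sqrt(area / (4.0 * ex0 * ey0))
    return a0 * scale, b0 * scale, ex0 * scale, ey0 * scale


def generate_scene(
    spec: SceneSpec, seed: Optional[int] = None
) -> tuple[np.ndarray, list[LabeledBox]]:
    """Render one scene; returns (H x W x 3 float image in [0, 1], boxes).

    Objects too large to fit inside the image are skipped with a warning.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = spec.image_size
    styles = class_styles(spec)
    areas = spec.class_mean_areas()

    # bright board with soft illumination gradient and sensor noise
    yy, xx = np.mgrid[0:h, 0:w]
    grad = 1.0 - 0.08 * ((yy / h - 0.5) ** 2 + (xx / w - 0.5) ** 2)
    img = spec.background_level * grad[..., None] * np.ones(3)
    img += rng.normal(0, 0.01, size=(h, w, 3))

    n_obj = int(rng.integers(spec.objects_per_image[0], spec.objects_per_image[1] + 1))
    labels: list[LabeledBox] = []
    for _ in range(n_obj):
        cls = int(rng.integers(1, spec.num_classes + 1))
        style = styles[cls - 1]
        area = float(areas[cls - 1] * rng.lognormal(0.0, 0.25))
        theta = float(rng.uniform(0, math.pi))
        a, b, ex, ey = _ellipse_extents(area, style.axis_ratio, theta)
        ex, ey = max(ex, 1.0), max(ey, 1.0)
        if w <= 2 * ex or h <= 2 * ey:
            warnings.warn(f"object of class {cls} too large to place; skipped")
            continue
        cx = float(rng.uniform(ex, w - ex))
        cy = float(rng.uniform(ey, h - ey))
        x0, x1 = int(math.floor(cx - ex)), int(math.ceil(cx + ex)) + 1
        y0, y1 = int(math.floor(cy - ey)), int(math.ceil(cy + ey)) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        py, px = np.mgrid[y0:y1, x0:x1]
        dx = (px + 0.5) - cx
        dy = (py + 0.5) - cy
        ct, st = math.cos(theta), math.sin(theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        stripes = 0.75 + 0.25 * np.sin(
            style.stripe_freq * u / max(a, 1e-6) * math.pi + style.stripe_phase
        )
        body = np.asarray(style.color)[None, None, :] * stripes[..., None]
        patch = img[y0:y1, x0:x1]
        patch[inside] = body[inside]
        labels.append(
            LabeledBox(
                Box(
                    max(cx - ex, 0.0), max(cy - ey, 0.0),
                    min(cx + ex, float(w)), min(cy + ey, float(h)),
                ),
                cls,
            )
        )
    img = np.clip(img, 0.0, 1.0)
    if spec.mist_sigma > 0:
        img = degrade_mist(img, spec.mist_sigma)
    return img.astype(np.float32), labels


def degrade_mist(image: np.ndarray, sigma: float) -> np.ndarray:
    """Water-mist degradation: Gaussian blur plus contrast loss toward the
    scene mean.  ``sigma=0`` returns the input unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image
    blurred = np.stack(
        [gaussian_filter(image[..., c], sigma) for c in range(image.shape[-1])],
        axis=-1,
    )
    contrast = 1.0 / (1.0 + 0.15 * sigma)
    mean = blurred.mean()
    return (mean + (blurred - mean) * contrast).astype(image.dtype)


def generate_dataset(
    spec: SceneSpec,
    n_images: int,
    out_dir: str | Path,
    split_fraction: float = 0.8,
) -> dict[str, Path]:
    """Write PNG images plus COCO ground-truth JSONs for a seeded
    train/test split; returns the written paths."""
    from PIL import Image

    from .evaluation import save_coco_ground_truth

    if n_images < 2:
        raise ValueError("need at least 2 images to split")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    gts: dict[int, list[LabeledBox]] = {}
    sizes: dict[int, tuple[int, int]] = {}
    for i in range(n_images):
        img, labels = generate_scene(spec, seed=spec.seed + 1000 + i)
        gts[i] = labels
        sizes[i] = spec.image_size
        Image.fromarray((img * 255).astype(np.uint8)).save(
            out_dir / "images" / f"{i:06d}.png"
        )
    order = rng.permutation(n_images)
    n_train = int(round(split_fraction * n_images))
    splits = {"train": sorted(order[:n_train]), "test": sorted(order[n_train:])}
    categories = {k: f"pest_{k:02d}" for k in range(1, spec.num_classes + 1)}
    paths: dict[str, Path] = {}
    for name, ids in splits.items():
        path = out_dir / f"{name}.json"
        save_coco_ground_truth(
            path,
            {int(i): gts[int(i)] for i in ids},
            {int(i): sizes[int(i)] for i in ids},
            categories,
        )
        paths[name] = path
    paths["images"] = out_dir / "images"
    return paths
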