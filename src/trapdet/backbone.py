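"""Feature pyramid containers and the small trainable 4-stage backbone.

The detector only assumes the *contract* encoded in :class:`FeaturePyramid`:
an ordered list of feature maps whose strides double level to level and
whose grids follow the ceil(size/stride) rule.  Any 4-stage extractor
(e.g. a ResNet's four block outputs) can stand behind it; the default
:class:`TinyBackbone` is small enough to train on a single CPU core and
needs no pretrained weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "FeatureMap",
    "FeaturePyramid",
    "BackboneConfig",
    "TinyBackbone",
    "extract_features",
    "resize_to_network",
]

_ALLOWED_STRIDES = (2, 4, 8, 16, 32, 64)


@dataclass
class FeatureMap:
    """A spatial grid of feature vectors plus its pixel stride.

    ``tensor`` is NCHW with N=1; ``stride`` is image pixels per grid cell.
    """

    tensor: Tensor
    stride: int

    def __post_init__(self) -> None:
        if self.stride not in _ALLOWED_STRIDES:
            raise ValueError(f"stride must be one of {_ALLOWED_STRIDES}")
        if self.tensor.ndim != 4 or self.tensor.shape[0] != 1:
            raise ValueError("feature map tensor must be [1, C, H, W]")
        if self.height < 1 or self.width < 1:
            raise ValueError("feature map must have positive spatial size")

    @property
    def channels(self) -> int:
        return self.tensor.shape[1]

    @property
    def height(self) -> int:
        return self.tensor.shape[2]

    @property
    def width(self) -> int:
        return self.tensor.shape[3]

    @property
    def grid(self) -> tuple[int, int]:
        return (self.height, self.width)


def expected_grid(image_size: tuple[int, int], stride: int) -> tuple[int, int]:
    """The ceil(size/stride) grid a level at ``stride`` must have."""
    h, w = image_size
    return (math.ceil(h / stride), math.ceil(w / stride))


@dataclass
class FeaturePyramid:
    """Ordered feature maps with strictly doubling strides."""

    levels: list[FeatureMap]
    image_size: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("pyramid must contain at least one level")
        strides = [lv.stride for lv in self.levels]
        for a, b in zip(strides, strides[1:]):
            if b != 2 * a:
                raise ValueError(f"strides must double level to level, got {strides}")
        for lv in self.levels:
            if lv.grid != expected_grid(self.image_size, lv.stride):
                raise ValueError(
                    f"level at stride {lv.stride} has grid {lv.grid}, expected "
                    f"{expected_grid(self.image_size, lv.stride)} for image {self.image_size}"
                )

    @property
    def strides(self) -> list[int]:
        return [lv.stride for lv in self.levels]

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, i: int) -> FeatureMap:
        return self.levels[i]


@dataclass(frozen=True)
class BackboneConfig:
    """Width/depth of the 4-stage extractor; strides are fixed at 4..32."""

    stage_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    stage_depth: int = 1
    min_image_size: int = 64

    def __post_init__(self) -> None:
        if len(self.stage_channels) != 4:
            raise ValueError("exactly 4 stage channel counts required")
        if any(c <= 0 for c in self.stage_channels):
            raise ValueError("stage channels must be positive")
        if any(b < a for a, b in zip(self.stage_channels, self.stage_channels[1:])):
            raise ValueError("stage channels must be non-decreasing")
        if self.stage_depth < 1:
            raise ValueError("stage_depth must be >= 1")

    stage_strides: tuple[int, int, int, int] = field(
        default=(4, 8, 16, 32), init=False
    )


class TinyBackbone(nn.Module):
    """Stride-2 stem followed by four stride-2 stages of 3x3 conv + ReLU.

    Each stage's first convolution downsamples (kernel 3, stride 2,
    padding 1, which realizes ceil-division grids for any input size);
    ``stage_depth - 1`` further stride-1 convolutions add capacity.
    Outputs after the four stages sit at strides 4, 8, 16 and 32.
    """

    def __init__(self, config: BackboneConfig = BackboneConfig(),
                 rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        ch = config.stage_channels
        self.stem = nn.Conv2d(3, ch[0], 3, stride=2, padding=1, rng=rng)
        self.stages: list[list[nn.Conv2d]] = []
        prev = ch[0]
        for c in ch:
            stage = [nn.Conv2d(prev, c, 3, stride=2, padding=1, rng=rng)]
            for _ in range(config.stage_depth - 1):
                stage.append(nn.Conv2d(c, c, 3, stride=1, padding=1, rng=rng))
            self.stages.append(stage)
            prev = c

    def __call__(self, image: np.ndarray | Tensor) -> FeaturePyramid:
        return extract_features(image, self)


def _as_nchw(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    return image.transpose(2, 0, 1)[None]


def extract_features(
    image: np.ndarray | Tensor, backbone: TinyBackbone
) -> FeaturePyramid:
    """Run the backbone on an H x W x 3 image (values in [0, 1]).

    Returns the 4-level pyramid at strides 4, 8, 16, 32.
    """
    if isinstance(image, Tensor):
        x = image
        h, w = x.shape[2], x.shape[3]
    else:
        arr = _as_nchw(image)
        h, w = arr.shape[2], arr.shape[3]
        x = Tensor(arr)
    m = backbone.config.min_image_size
    if h < m or w < m:
        raise ValueError(f"image must be at least {m}x{m}, got {h}x{w}")
    x = nn.relu(backbone.stem(x))
    levels = []
    for stage, stride in zip(backbone.stages, backbone.config.stage_strides):
        for conv in stage:
            x = nn.relu(conv(x))
        levels.append(FeatureMap(x, stride))
    return FeaturePyramid(levels, (h, w))


def resize_to_network(
    image: np.ndarray, short_side: int = 800, max_long_side: int = 1088
) -> tuple[np.ndarray, float]:
    """Scale so the shorter side hits ``short_side`` without the longer
    side exceeding ``max_long_side``; returns (resized image, scale).

    2,592 x 1,944 field captures map to 1,066 x 800 under the defaults.
    """
    from scipy.ndimage import zoom

    h, w = image.shape[:2]
    scale = min(short_side / min(h, w), max_long_side / max(h, w))
    if math.isclose(scale, 1.0):
        return np.asarray(image, dtype=np.float32), 1.0
    out = zoom(np.asarray(image, dtype=np.float32), (scale, scale, 1), order=1)
    return out, scale
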