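import numpy as np
import pytest

from trapdet.anchors import AnchorConfig
from trapdet.backbone import BackboneConfig
from trapdet.detector import Detector, DetectorConfig
from trapdet.neck import MSRConfig
from trapdet.scenes import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def desk_detector_config(num_classes: int = 3) -> DetectorConfig:
    """Small-footprint detector used across tests: tiny backbone widths,
    32-channel neck, sub-stride anchors for the very small objects."""
    return DetectorConfig(
        num_classes=num_classes,
        backbone=BackboneConfig((8, 16, 32, 48)),
        msr=MSRConfig(out_channels=32),
        anchors=AnchorConfig(size_per_stride=2.0, ratios=(0.5, 1.0, 2.0)),
    )


def desk_scenes(n: int = 5, image_size=(256, 320), num_classes: int = 3, seed: int = 0):
    """Render ``n`` fixed scenes; returns (images, (boxes, labels) pairs,
    per-image ground-truth dict)."""
    spec = SceneSpec(
        image_size=image_size, num_classes=num_classes,
        objects_per_image=(3, 6), seed=seed,
    )
    images, targets, gts = [], [], {}
    for i in range(n):
        img, labels = generate_scene(spec, seed=100 + i)
        images.append(img)
        gts[i] = labels
        boxes = np.array([l.box.as_array() for l in labels]).reshape(-1, 4)
        cls = np.array([l.class_id for l in labels], dtype=np.int64)
        targets.append((boxes, cls))
    return images, targets, gts


@pytest.fixture
def tiny_detector():
    return Detector(desk_detector_config(), seed=0)
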