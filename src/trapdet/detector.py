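"""Minimal two-stage detector hosting the enhancement neck and Soft-IoU.

Pipeline per image: backbone pyramid -> neck (5 levels, strides 4..64) ->
RPN objectness/deltas per anchor -> proposal selection (decode, clip, NMS,
top-k) -> RoIAlign -> classification + box-regression head.

Training follows the two-stage protocol: per-image SGD mini-batches of 256
RoI samples drawn 1:1 positive:negative, up to 1,000 proposals forwarded to
the second stage, L1 regression loss in the RPN and SmoothL1 in the R-CNN
head, cross-entropy for both classifications.  Candidate-to-ground-truth
assignment scores candidates with Soft-IoU (beta = 0.9) against the usual
0.5 threshold, so an overlapping but badly centered candidate can drop below
the positive cut that its plain IoU would clear.  At test time duplicate
removal uses Soft-IoU with beta = 1.1, retaining slightly off-center
duplicates as independent detections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .anchors import (
    AnchorConfig,
    clip_boxes,
    decode_deltas,
    encode_deltas,
    generate_anchors,
    nms,
)
from .backbone import BackboneConfig, FeaturePyramid, TinyBackbone, extract_features
from .boxes import Box, SoftIoUConfig, pairwise_iou, pairwise_soft_iou
from .neck import MSRConfig, build_neck
from .nn import Tensor

__all__ = [
    "SamplerConfig",
    "RPNConfig",
    "Detection",
    "DetectorConfig",
    "TrainingDivergence",
    "assign_targets",
    "sample_minibatch",
    "roi_align",
    "Detector",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Positive/negative assignment and mini-batch composition."""

    samples_per_image: int = 256
    positive_fraction: float = 0.5
    assign_score: str = "soft_iou"  # soft_iou | iou
    positive_threshold: float = 0.5
    negative_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must lie in (0, 1)")
        for t in (self.positive_threshold, self.negative_threshold):
            if not (0.0 <= t <= 1.1):
                raise ValueError("thresholds must lie in [0, 1.1]")
        if self.assign_score not in ("soft_iou", "iou"):
            raise ValueError("assign_score must be 'soft_iou' or 'iou'")


@dataclass(frozen=True)
class RPNConfig:
    num_proposals: int = 1000
    pre_nms_top: int = 2000
    nms_threshold: float = 0.7
    min_box_size: float = 1.0

    def __post_init__(self) -> None:
        if self.num_proposals <= 0:
            raise ValueError("num_proposals must be positive")


@dataclass(frozen=True)
class Detection:
    box: Box
    class_id: int
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("detection score must be finite")
        if self.class_id < 1:
            raise ValueError("class_id must be >= 1 (0 is background)")


class TrainingDivergence(RuntimeError):
    """Raised when a loss turns non-finite; carries the loss diagnostics."""


# -- assignment and sampling ------------------------------------------


def assign_targets(
    candidates: np.ndarray,
    gt_boxes: np.ndarray,
    sampler: SamplerConfig = SamplerConfig(),
    si_config: SoftIoUConfig = SoftIoUConfig(),
    phase: str = "train",
) -> tuple[np.ndarray, np.ndarray]:
    """Label candidates positive (1) / negative (0) / ignore (-1).

    A candidate is positive when its best assignment score over ground
    truths clears ``positive_threshold``, or when it is the best candidate
    for some ground truth (argmax rescue, so every object trains at least
    one sample).  Scores are Soft-IoU with the training-phase beta, or
    plain IoU under the ablation switch.  Ties pick the lowest ground-truth
    index.  Returns ``(labels, matched_gt_index)``; matched index is -1 for
    non-positives.
    """
    n = len(candidates)
    labels = np.zeros(n, dtype=np.int8)
    matched = np.full(n, -1, dtype=np.int64)
    if len(gt_boxes) == 0:
        return labels, matched
    if sampler.assign_score == "soft_iou":
        score = pairwise_soft_iou(
            candidates, gt_boxes,
            beta=si_config.beta(phase), clamp_factor=si_config.clamp_factor,
        )
    else:
        score = pairwise_iou(candidates, gt_boxes)
    best = score.max(axis=1)
    best_gt = score.argmax(axis=1)  # lowest gt index on ties
    labels[best >= sampler.positive_threshold] = 1
    labels[best < sampler.negative_threshold] = 0
    between = (best >= sampler.negative_threshold) & (
        best < sampler.positive_threshold
    )
    labels[between] = -1
    labels[best < sampler.negative_threshold] = 0
    matched[labels == 1] = best_gt[labels == 1]
    # argmax rescue: every gt with any overlap gets its best candidate
    for j in range(score.shape[1]):
        col = score[:, j]
        if col.max() <= 0.0:
            continue
        i = int(col.argmax())
        labels[i] = 1
        matched[i] = j
    return labels, matched


def sample_minibatch(
    labels: np.ndarray,
    sampler: SamplerConfig,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw up to ``samples_per_image`` indices at the target 1:1 ratio;
    scarce positives are backfilled with negatives."""
    if len(labels) == 0:
        raise ValueError("cannot sample from zero candidates")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n_pos = min(len(pos), int(round(sampler.samples_per_image * sampler.positive_fraction)))
    n_neg = min(len(neg), sampler.samples_per_image - n_pos)
    sel_pos = rng.choice(pos, size=n_pos, replace=False) if n_pos else np.zeros(0, np.int64)
    sel_neg = rng.choice(neg, size=n_neg, replace=False) if n_neg else np.zeros(0, np.int64)
    return np.concatenate([sel_pos, sel_neg]).astype(np.int64)


# -- RoIAlign ----------------------------------------------------------


def roi_align(
    feature: Tensor, boxes: np.ndarray, stride: int, output_size: int = 7
) -> Tensor:
    """Quantization-free pooling to ``output_size**2`` bins.

    Each bin is sampled bilinearly at its center in continuous feature
    coordinates (feature cell centers at ``(i + 0.5) * stride`` image
    pixels), differentiable w.r.t. the feature map.
    """
    boxes = np.asarray(boxes, dtype=np.float64)
    if np.any(boxes[:, 2] <= boxes[:, 0]) or np.any(boxes[:, 3] <= boxes[:, 1]):
        raise ValueError("degenerate box passed to roi_align")
    n = len(boxes)
    _, c, h, w = feature.shape
    s = output_size
    # bin-center sample points, continuous feature coords
    steps = (np.arange(s) + 0.5) / s
    xs = (boxes[:, 0:1] + steps[None, :] * (boxes[:, 2:3] - boxes[:, 0:1])) / stride - 0.5
    ys = (boxes[:, 1:2] + steps[None, :] * (boxes[:, 3:4] - boxes[:, 1:2])) / stride - 0.5
    xs = np.clip(xs, 0.0, w - 1.0)
    ys = np.clip(ys, 0.0, h - 1.0)
    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = (xs - x0).astype(np.float32)
    fy = (ys - y0).astype(np.float32)
    # broadcast to [n, s, s]
    Y0 = np.broadcast_to(y0[:, :, None], (n, s, s))
    Y1 = np.broadcast_to(y1[:, :, None], (n, s, s))
    X0 = np.broadcast_to(x0[:, None, :], (n, s, s))
    X1 = np.broadcast_to(x1[:, None, :], (n, s, s))
    WY = fy[:, :, None]
    WX = fx[:, None, :]
    w00 = ((1 - WY) * (1 - WX)).astype(np.float32)
    w01 = ((1 - WY) * WX).astype(np.float32)
    w10 = (WY * (1 - WX)).astype(np.float32)
    w11 = (WY * WX).astype(np.float32)
    d = feature.data[0]  # [C, H, W]
    out = (
        d[:, Y0, X0] * w00 + d[:, Y0, X1] * w01
        + d[:, Y1, X0] * w10 + d[:, Y1, X1] * w11
    ).transpose(1, 0, 2, 3).astype(np.float32)  # [n, C, s, s]

    def backward(g):
        buf = np.zeros_like(feature.data)
        gt = g.transpose(1, 0, 2, 3)  # [C, n, s, s]
        np.add.at(buf[0], (slice(None), Y0, X0), gt * w00)
        np.add.at(buf[0], (slice(None), Y0, X1), gt * w01)
        np.add.at(buf[0], (slice(None), Y1, X0), gt * w10)
        np.add.at(buf[0], (slice(None), Y1, X1), gt * w11)
        feature._accumulate(buf)

    return Tensor._result(out, (feature,), backward)


def _roi_levels(boxes: np.ndarray, num_levels: int, canonical: float = 56.0) -> np.ndarray:
    """Size-based pyramid level choice: sqrt(area) around ``canonical``
    pixels maps to the stride-4 level, each doubling moves one level up."""
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    lvl = np.floor(np.log2(np.sqrt(np.maximum(areas, 1e-6)) / canonical + 1e-9))
    return np.clip(lvl, 0, num_levels - 1).astype(np.int64)


# -- model -------------------------------------------------------------


@dataclass(frozen=True)
class DetectorConfig:
    num_classes: int = 8
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    neck: str = "msr"  # msr | fpn-baseline
    msr: MSRConfig = field(default_factory=MSRConfig)
    anchors: AnchorConfig = field(default_factory=AnchorConfig)
    rpn: RPNConfig = field(default_factory=RPNConfig)
    rpn_sampler: SamplerConfig = field(
        default_factory=lambda: SamplerConfig(samples_per_image=256)
    )
    roi_sampler: SamplerConfig = field(default_factory=SamplerConfig)
    soft_iou: SoftIoUConfig = field(default_factory=SoftIoUConfig)
    roi_size: int = 7
    head_hidden: int = 256
    score_threshold: float = 0.05
    test_nms_threshold: float = 0.5
    test_overlap: str = "soft_iou"  # soft_iou | iou
    max_detections: int = 100


class RPNHead(nn.Module):
    """Shared 3x3 conv + per-anchor objectness and 4-delta 1x1 heads."""

    def __init__(self, channels: int, num_anchors: int, rng: np.random.Generator):
        self.num_anchors = num_anchors
        self.conv = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.obj = nn.Conv2d(channels, num_anchors, 1, rng=rng, init="gaussian")
        self.reg = nn.Conv2d(channels, 4 * num_anchors, 1, rng=rng, init="gaussian")

    def __call__(self, level: Tensor) -> tuple[Tensor, Tensor]:
        t = nn.relu(self.conv(level))
        a = self.num_anchors
        _, _, h, w = t.shape
        obj = self.obj(t).reshape(a, h, w).transpose(1, 2, 0).reshape(h * w * a)
        reg = (
            self.reg(t)
            .reshape(a, 4, h, w)
            .transpose(2, 3, 0, 1)
            .reshape(h * w * a, 4)
        )
        return obj, reg


class RoIHead(nn.Module):
    """Two-layer MLP head: (K+1)-way classification + class-agnostic box."""

    def __init__(self, in_features: int, hidden: int, num_classes: int,
                 rng: np.random.Generator):
        self.fc = nn.Linear(in_features, hidden, rng=rng)
        # mean-0, sd-0.01 Gaussian init for the classification-regression layers
        self.cls = nn.Linear(hidden, num_classes + 1, rng=rng, init="gaussian")
        self.reg = nn.Linear(hidden, 4, rng=rng, init="gaussian")

    def __call__(self, feats: Tensor) -> tuple[Tensor, Tensor]:
        h = nn.relu(self.fc(feats))
        return self.cls(h), self.reg(h)


class Detector(nn.Module):
    def __init__(self, config: DetectorConfig = DetectorConfig(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.backbone = TinyBackbone(config.backbone, rng=rng)
        self.neck = build_neck(
            config.neck, config.backbone.stage_channels, config.msr, rng=rng
        )
        oc = config.msr.out_channels
        self.rpn_head = RPNHead(oc, len(config.anchors.ratios), rng)
        self.roi_head = RoIHead(
            oc * config.roi_size**2, config.head_hidden, config.num_classes, rng
        )

    # -- forward pieces ------------------------------------------------

    def forward_features(self, image: np.ndarray) -> FeaturePyramid:
        return self.neck(extract_features(image, self.backbone))

    def rpn_forward(self, pyramid: FeaturePyramid) -> tuple[Tensor, Tensor]:
        objs, regs = [], []
        for lv in pyramid.levels:
            o, r = self.rpn_head(lv.tensor)
            objs.append(o)
            regs.append(r)
        return nn.concat(objs, axis=0), nn.concat(regs, axis=0)

    def select_proposals(
        self,
        anchors: np.ndarray,
        obj: np.ndarray,
        deltas: np.ndarray,
        image_size: tuple[int, int],
    ) -> np.ndarray:
        """Decode, clip, filter tiny boxes, NMS, keep top num_proposals."""
        cfg = self.config.rpn
        order = np.argsort(-obj, kind="stable")[: cfg.pre_nms_top]
        boxes = decode_deltas(anchors[order], deltas[order])
        boxes = clip_boxes(boxes, image_size)
        wh = np.minimum(boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1])
        good = wh >= cfg.min_box_size
        boxes, scores = boxes[good], obj[order][good]
        keep = nms(boxes, scores, cfg.nms_threshold, overlap="iou")
        return boxes[keep[: cfg.num_proposals]]

    def roi_features(self, pyramid: FeaturePyramid, boxes: np.ndarray) -> Tensor:
        """Pool each box from its size-matched level; preserves box order."""
        levels = _roi_levels(boxes, len(pyramid))
        n = len(boxes)
        pieces: list[Tensor] = []
        index: list[np.ndarray] = []
        for li, lv in enumerate(pyramid.levels):
            sel = np.flatnonzero(levels == li)
            if len(sel) == 0:
                continue
            pieces.append(
                roi_align(lv.tensor, boxes[sel], lv.stride, self.config.roi_size)
            )
            index.append(sel)
        pooled = nn.concat(pieces, axis=0)
        order = np.argsort(np.concatenate(index), kind="stable")
        pooled = pooled[order]
        return pooled.reshape(n, -1)

    # -- training ------------------------------------------------------

    def compute_losses(
        self,
        image: np.ndarray,
        gt_boxes: np.ndarray,
        gt_labels: np.ndarray,
        rng: np.random.Generator,
    ) -> dict[str, Tensor]:
        """Per-image losses: RPN cross-entropy + L1, head cross-entropy +
        SmoothL1.  Raises :class:`TrainingDivergence` on non-finite loss."""
        cfg = self.config
        pyramid = self.forward_features(image)
        image_size = pyramid.image_size
        anchor_list = generate_anchors(image_size, pyramid, cfg.anchors)
        anchors = np.concatenate(anchor_list, axis=0)
        obj, reg = self.rpn_forward(pyramid)

        # RPN targets (class-agnostic)
        labels, matched = assign_targets(
            anchors, gt_boxes, cfg.rpn_sampler, cfg.soft_iou, phase="train"
        )
        sel = sample_minibatch(labels, cfg.rpn_sampler, rng)
        sel_t = obj[sel]
        rpn_cls = nn.bce_with_logits(sel_t, (labels[sel] == 1).astype(np.float32))
        pos = sel[labels[sel] == 1]
        if len(pos) > 0:
            targets = encode_deltas(gt_boxes[matched[pos]], anchors[pos])
            rpn_reg = nn.l1_loss(reg[pos], targets)
        else:
            rpn_reg = Tensor(np.float32(0.0))

        # proposals (no gradient through box coordinates)
        with nn.no_grad():
            proposals = self.select_proposals(
                anchors, obj.data.astype(np.float64), reg.data.astype(np.float64),
                image_size,
            )
        if len(gt_boxes) > 0:
            proposals = np.concatenate([proposals, gt_boxes], axis=0)

        # second-stage targets
        p_labels, p_matched = assign_targets(
            proposals, gt_boxes, cfg.roi_sampler, cfg.soft_iou, phase="train"
        )
        p_sel = sample_minibatch(p_labels, cfg.roi_sampler, rng)
        feats = self.roi_features(pyramid, proposals[p_sel])
        cls_logits, box_deltas = self.roi_head(feats)
        cls_targets = np.where(
            p_labels[p_sel] == 1, gt_labels[p_matched[p_sel]], 0
        ).astype(np.int64)
        rcnn_cls = nn.softmax_cross_entropy(cls_logits, cls_targets)
        pos_mask = p_labels[p_sel] == 1
        if pos_mask.any():
            pidx = np.flatnonzero(pos_mask)
            targets = encode_deltas(
                gt_boxes[p_matched[p_sel][pidx]], proposals[p_sel][pidx]
            )
            rcnn_reg = nn.smooth_l1_loss(box_deltas[pidx], targets)
        else:
            rcnn_reg = Tensor(np.float32(0.0))

        losses = {
            "rpn_cls": rpn_cls,
            "rpn_reg": rpn_reg,
            "rcnn_cls": rcnn_cls,
            "rcnn_reg": rcnn_reg,
        }
        diag = {k: float(v.data) for k, v in losses.items()}
        if not all(np.isfinite(v) for v in diag.values()):
            raise TrainingDivergence(f"non-finite loss: {diag}")
        return losses

    # -- inference -----------------------------------------------------

    def infer(self, image: np.ndarray) -> list[Detection]:
        """Detections after score thresholding and per-class NMS; the
        duplicate-removal overlap is Soft-IoU with the test-phase beta."""
        cfg = self.config
        with nn.no_grad():
            pyramid = self.forward_features(image)
            anchor_list = generate_anchors(pyramid.image_size, pyramid, cfg.anchors)
            anchors = np.concatenate(anchor_list, axis=0)
            obj, reg = self.rpn_forward(pyramid)
            proposals = self.select_proposals(
                anchors, obj.data.astype(np.float64), reg.data.astype(np.float64),
                pyramid.image_size,
            )
            if len(proposals) == 0:
                return []
            feats = self.roi_features(pyramid, proposals)
            cls_logits, box_deltas = self.roi_head(feats)
            probs = nn.softmax(cls_logits, axis=1).data
            boxes = decode_deltas(proposals, box_deltas.data.astype(np.float64))
            boxes = clip_boxes(boxes, pyramid.image_size)
        detections: list[Detection] = []
        for k in range(1, cfg.num_classes + 1):
            scores = probs[:, k]
            good = scores >= cfg.score_threshold
            wh = np.minimum(boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1])
            good &= wh > 0
            if not good.any():
                continue
            b, s = boxes[good], scores[good]
            keep = nms(
                b, s, cfg.test_nms_threshold,
                overlap=cfg.test_overlap,
                beta=cfg.soft_iou.beta_test,
                clamp_factor=cfg.soft_iou.clamp_factor,
            )
            for i in keep:
                detections.append(Detection(Box(*b[i]), k, float(s[i])))
        detections.sort(key=lambda d: -d.score)
        return detections[: cfg.max_detections]


# -- checkpoints -------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: Detector, path: str | Path, extra: Optional[dict] = None) -> None:
    path = Path(path)
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": _config_to_dict(model.config),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> Detector:
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = Detector(_config_from_dict(meta["config"]))
    model.load_state_dict(state)
    return model


def _config_to_dict(cfg: DetectorConfig) -> dict:
    import dataclasses

    def conv(obj):
        if dataclasses.is_dataclass(obj):
            return {
                f.name: conv(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
                if f.init
            }
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return conv(cfg)


def _config_from_dict(d: dict) -> DetectorConfig:
    return DetectorConfig(
        num_classes=d["num_classes"],
        backbone=BackboneConfig(tuple(d["backbone"]["stage_channels"]),
                                d["backbone"]["stage_depth"],
                                d["backbone"]["min_image_size"]),
        neck=d["neck"],
        msr=MSRConfig(**d["msr"]),
        anchors=AnchorConfig(d["anchors"]["size_per_stride"], tuple(d["anchors"]["ratios"])),
        rpn=RPNConfig(**d["rpn"]),
        rpn_sampler=SamplerConfig(**d["rpn_sampler"]),
        roi_sampler=SamplerConfig(**d["roi_sampler"]),
        soft_iou=SoftIoUConfig(**d["soft_iou"]),
        roi_size=d["roi_size"],
        head_hidden=d["head_hidden"],
        score_threshold=d["score_threshold"],
        test_nms_threshold=d["test_nms_threshold"],
        test_overlap=d["test_overlap"],
        max_detections=d["max_detections"],
    )
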