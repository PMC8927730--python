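"""Run configuration: YAML-backed, schema-validated, fully serialized.

A :class:`RunConfig` mirrors the library dataclasses section by section;
unknown keys are rejected so typos fail loudly.  One root ``seed`` governs
every randomized path (weight init, sampling, scene generation), and the
resolved configuration is echoed into each run's output directory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict

from .anchors import AnchorConfig
from .backbone import BackboneConfig
from .boxes import SoftIoUConfig
from .detector import DetectorConfig, RPNConfig, SamplerConfig
from .evaluation import EvalConfig
from .neck import MSRConfig
from .scenes import SceneSpec
from .train import TrainConfig

__all__ = ["RunConfig", "load_run_config", "save_run_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BackboneSection(_Strict):
    stage_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    stage_depth: int = 1


class NeckSection(_Strict):
    kind: Literal["msr", "fpn-baseline"] = "msr"
    out_channels: int = 256
    alpha: float = 0.5
    learnable_alpha: bool = False
    local_normalization: Literal["mean", "none"] = "mean"
    channel_gate: Literal["literal", "sigmoid"] = "literal"


class SoftIoUSection(_Strict):
    beta_train: float = 0.9
    beta_test: float = 1.1
    clamp_factor: float = 0.1


class SamplerSection(_Strict):
    samples_per_image: int = 256
    positive_fraction: float = 0.5
    assign_score: Literal["soft_iou", "iou"] = "soft_iou"
    positive_threshold: float = 0.5
    negative_threshold: float = 0.5


class RPNSection(_Strict):
    num_proposals: int = 1000
    pre_nms_top: int = 2000
    nms_threshold: float = 0.7


class AnchorSection(_Strict):
    size_per_stride: float = 4.0
    ratios: tuple[float, ...] = (1.0,)


class TrainingSection(_Strict):
    epochs: int = 12
    lr: float = 0.0025
    lr_drop_epoch: int = 8
    lr_drop_factor: float = 10.0
    momentum: float = 0.9
    iterations: Optional[int] = None


class DatasetSection(_Strict):
    image_size: tuple[int, int] = (800, 1088)
    num_classes: int = 8
    objects_per_image: tuple[int, int] = (3, 12)
    relative_area: float = 0.0158
    reference_box_fraction: float = 0.38
    scale_spread: float = 32.0
    similarity_pairs: tuple[tuple[int, int], ...] = ()
    similarity_epsilon: float = 0.15
    mist_sigma: float = 0.0
    n_images: int = 10


class EvaluationSection(_Strict):
    mode: Literal["triple", "coco"] = "triple"
    overlap_measure: Literal["iou", "soft_iou"] = "iou"


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs/default"
    backbone: BackboneSection = BackboneSection()
    neck: NeckSection = NeckSection()
    soft_iou: SoftIoUSection = SoftIoUSection()
    rpn: RPNSection = RPNSection()
    rpn_sampler: SamplerSection = SamplerSection()
    roi_sampler: SamplerSection = SamplerSection()
    anchors: AnchorSection = AnchorSection()
    training: TrainingSection = TrainingSection()
    dataset: DatasetSection = DatasetSection()
    evaluation: EvaluationSection = EvaluationSection()
    score_threshold: float = 0.05
    test_nms_threshold: float = 0.5
    test_overlap: Literal["soft_iou", "iou"] = "soft_iou"

    # -- builders ------------------------------------------------------

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(
            num_classes=self.dataset.num_classes,
            backbone=BackboneConfig(
                tuple(self.backbone.stage_channels), self.backbone.stage_depth
            ),
            neck=self.neck.kind,
            msr=MSRConfig(
                out_channels=self.neck.out_channels,
                alpha=self.neck.alpha,
                learnable_alpha=self.neck.learnable_alpha,
                local_normalization=self.neck.local_normalization,
                channel_gate=self.neck.channel_gate,
            ),
            anchors=AnchorConfig(
                self.anchors.size_per_stride, tuple(self.anchors.ratios)
            ),
            rpn=RPNConfig(
                num_proposals=self.rpn.num_proposals,
                pre_nms_top=self.rpn.pre_nms_top,
                nms_threshold=self.rpn.nms_threshold,
            ),
            rpn_sampler=SamplerConfig(**self.rpn_sampler.model_dump()),
            roi_sampler=SamplerConfig(**self.roi_sampler.model_dump()),
            soft_iou=SoftIoUConfig(**self.soft_iou.model_dump()),
            score_threshold=self.score_threshold,
            test_nms_threshold=self.test_nms_threshold,
            test_overlap=self.test_overlap,
        )

    def scene_spec(self) -> SceneSpec:
        d = self.dataset
        return SceneSpec(
            image_size=tuple(d.image_size),
            num_classes=d.num_classes,
            objects_per_image=tuple(d.objects_per_image),
            relative_area=d.relative_area,
            reference_box_fraction=d.reference_box_fraction,
            scale_spread=d.scale_spread,
            similarity_pairs=tuple(tuple(p) for p in d.similarity_pairs),
            similarity_epsilon=d.similarity_epsilon,
            mist_sigma=d.mist_sigma,
            seed=self.seed,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(**self.training.model_dump())

    def eval_config(self) -> EvalConfig:
        return EvalConfig(
            mode=self.evaluation.mode,
            overlap_measure=self.evaluation.overlap_measure,
            soft_iou_beta=self.soft_iou.beta_test,
            soft_iou_clamp=self.soft_iou.clamp_factor,
        )


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        doc = yaml.safe_load(f) or {}
    return RunConfig.model_validate(doc)


def save_run_config(config: RunConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(config.model_dump(mode="json"), f, sort_keys=False)
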