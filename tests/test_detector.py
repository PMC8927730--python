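"""Detector-core tests: anchors, Soft-IoU assignment, sampling, RoIAlign,
proposal plumbing, losses, and checkpointing."""

import numpy as np
import pytest

from trapdet.anchors import (AnchorConfig, clip_boxes, decode_deltas,
                             encode_deltas, generate_anchors, nms)
from trapdet.backbone import BackboneConfig, TinyBackbone
from trapdet.boxes import Box, SoftIoUConfig, iou, pairwise_iou, soft_iou
from trapdet.detector import (Detector, SamplerConfig, TrainingDivergence,
                              assign_targets, load_checkpoint, roi_align,
                              sample_minibatch, save_checkpoint)
from trapdet.nn import Tensor
from trapdet.train import TrainConfig, train_detector

from conftest import desk_detector_config, desk_scenes


class TestAnchors:
    def test_count_per_level(self):
        bb = TinyBackbone(BackboneConfig((4, 8, 8, 8)), rng=np.random.default_rng(0))
        pyr = bb(np.zeros((100, 136, 3), np.float32))
        anchors = generate_anchors((100, 136), pyr, AnchorConfig(ratios=(1.0,)))
        assert [len(a) for a in anchors] == [25 * 34, 13 * 17, 7 * 9, 4 * 5]

    def test_centers_on_cell_centers(self):
        bb = TinyBackbone(BackboneConfig((4, 8, 8, 8)), rng=np.random.default_rng(0))
        pyr = bb(np.zeros((64, 64, 3), np.float32))
        anchors = generate_anchors((64, 64), pyr, AnchorConfig(ratios=(1.0,)))
        a0 = anchors[0]  # stride 4
        cx = 0.5 * (a0[:, 0] + a0[:, 2])
        assert cx[0] == pytest.approx(4 * 0.5)
        assert cx[1] == pytest.approx(4 * 1.5)

    def test_anchors_unclipped(self):
        bb = TinyBackbone(BackboneConfig((4, 8, 8, 8)), rng=np.random.default_rng(0))
        pyr = bb(np.zeros((64, 64, 3), np.float32))
        anchors = generate_anchors((64, 64), pyr, AnchorConfig(size_per_stride=8.0))
        assert (anchors[-1][:, 0] < 0).any()  # big anchors spill off the image
        clipped = clip_boxes(anchors[-1], (64, 64))
        assert clipped.min() >= 0 and clipped.max() <= 64

    def test_delta_coding_roundtrip(self, rng):
        anchors = np.c_[rng.uniform(0, 50, (20, 2)), rng.uniform(60, 100, (20, 2))]
        boxes = np.c_[rng.uniform(0, 50, (20, 2)), rng.uniform(60, 100, (20, 2))]
        rec = decode_deltas(anchors, encode_deltas(boxes, anchors))
        assert np.allclose(rec, boxes, atol=1e-9)


class TestAssignment:
    def test_identical_candidate_is_positive_under_training_beta(self):
        gt = np.array([[10.0, 10.0, 30.0, 30.0]])
        labels, matched = assign_targets(gt.copy(), gt)
        # SI(A, A) = 0.9 >= 0.5
        assert labels[0] == 1 and matched[0] == 0

    def test_empty_gt_all_negative(self, rng):
        cands = np.c_[rng.uniform(0, 20, (15, 2)), rng.uniform(30, 50, (15, 2))]
        labels, matched = assign_targets(cands, np.zeros((0, 4)))
        assert np.all(labels == 0) and np.all(matched == -1)

    def test_soft_iou_demotes_offcenter_candidate_iou_would_accept(self):
        # IoU 0.55 but center shifted: SI = 0.9 * 0.55 = 0.495 < 0.5
        gt = np.array([[0.0, 0.0, 10.0, 10.0]])
        d = 10 * 0.45 / 1.55  # shift giving IoU exactly 0.55
        cand = np.array([[d, 0.0, 10.0 + d, 10.0]])
        val = iou(Box(*cand[0]), Box(*gt[0]))
        assert val == pytest.approx(0.55, abs=1e-12)
        si = soft_iou(Box(*cand[0]), Box(*gt[0]), beta=0.9)
        assert si == pytest.approx(0.495, abs=1e-9)
        # far candidate present so argmax rescue lands elsewhere
        far = np.array([[0.0, 0.0, 10.0, 10.0]])
        cands = np.vstack([cand, far])
        labels_si, _ = assign_targets(cands, gt, SamplerConfig())
        labels_iou, _ = assign_targets(cands, gt, SamplerConfig(assign_score="iou"))
        assert labels_si[0] == 0 and labels_iou[0] == 1

    def test_ablation_switch_reproduces_hard_iou_decisions(self, rng):
        cands = np.c_[rng.uniform(0, 40, (200, 2)), rng.uniform(45, 90, (200, 2))]
        gt = np.c_[rng.uniform(0, 40, (4, 2)), rng.uniform(45, 90, (4, 2))]
        labels, matched = assign_targets(cands, gt, SamplerConfig(assign_score="iou"))
        # reference hard-IoU assigner, written directly from the rule
        mat = pairwise_iou(cands, gt)
        ref_labels = (mat.max(axis=1) >= 0.5).astype(np.int8)
        ref_matched = np.where(ref_labels == 1, mat.argmax(axis=1), -1)
        for j in range(4):
            if mat[:, j].max() > 0:
                i = mat[:, j].argmax()
                ref_labels[i] = 1
                ref_matched[i] = j
        assert np.array_equal(labels, ref_labels)
        assert np.array_equal(matched, ref_matched)

    def test_argmax_rescue_gives_every_gt_a_positive(self, rng):
        # tiny gt overlapped by no candidate above threshold
        cands = np.array([[0.0, 0.0, 8.0, 8.0], [20.0, 20.0, 30.0, 30.0]])
        gt = np.array([[1.0, 1.0, 3.0, 3.0]])
        labels, matched = assign_targets(cands, gt)
        assert labels[0] == 1 and matched[0] == 0


class TestSampler:
    def test_balanced_when_both_abundant(self, rng):
        labels = np.array([1] * 300 + [0] * 300, dtype=np.int8)
        sel = sample_minibatch(labels, SamplerConfig(), rng)
        assert len(sel) == 256
        assert (labels[sel] == 1).sum() == 128
        assert (labels[sel] == 0).sum() == 128

    def test_negatives_backfill_scarce_positives(self, rng):
        labels = np.array([1] * 10 + [0] * 500, dtype=np.int8)
        sel = sample_minibatch(labels, SamplerConfig(), rng)
        assert (labels[sel] == 1).sum() == 10
        assert (labels[sel] == 0).sum() == 246

    def test_seed_reproducibility(self):
        labels = np.array([1] * 50 + [0] * 400, dtype=np.int8)
        s1 = sample_minibatch(labels, SamplerConfig(), 42)
        s2 = sample_minibatch(labels, SamplerConfig(), 42)
        assert np.array_equal(s1, s2)

    def test_zero_candidates_error(self):
        with pytest.raises(ValueError):
            sample_minibatch(np.zeros(0, np.int8), SamplerConfig(), 0)


class TestNMS:
    def test_duplicate_suppressed(self):
        boxes = np.array([[0, 0, 10, 10], [0.5, 0, 10.5, 10]], dtype=float)
        keep = nms(boxes, np.array([0.9, 0.8]), 0.5)
        assert list(keep) == [0]

    def test_idempotent(self, rng):
        boxes = np.c_[rng.uniform(0, 50, (30, 2)), rng.uniform(55, 100, (30, 2))]
        scores = rng.uniform(0, 1, 30)
        keep1 = nms(boxes, scores, 0.5)
        keep2 = keep1[nms(boxes[keep1], scores[keep1], 0.5)]
        assert np.array_equal(keep1, keep2)

    def test_soft_iou_retains_offcenter_pair_that_iou_suppresses(self):
        # IoU 0.52 > 0.5 but SI = 0.9 * 0.52 = 0.468 < 0.5 (clamp floor)
        d = 10 * 0.48 / 1.52
        boxes = np.array([[0, 0, 10, 10], [d, 0, 10 + d, 10]])
        scores = np.array([0.9, 0.8])
        assert iou(Box(*boxes[0]), Box(*boxes[1])) > 0.5
        keep_iou = nms(boxes, scores, 0.5, overlap="iou")
        keep_si = nms(boxes, scores, 0.5, overlap="soft_iou", beta=1.1)
        assert len(keep_iou) == 1 and len(keep_si) == 2


class TestRoIAlign:
    def test_constant_map_pools_constant(self):
        feat = Tensor(np.full((1, 3, 8, 8), 2.5, np.float32))
        out = roi_align(feat, np.array([[4.0, 4.0, 20.0, 20.0]]), stride=4, output_size=7)
        assert out.shape == (1, 3, 7, 7)
        assert np.allclose(out.data, 2.5, atol=1e-6)

    def test_degenerate_box_rejected(self):
        feat = Tensor(np.zeros((1, 1, 8, 8), np.float32))
        with pytest.raises(ValueError):
            roi_align(feat, np.array([[5.0, 5.0, 5.0, 9.0]]), stride=1)

    def test_matches_dense_bilinear_oracle(self, rng):
        feat = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        box = np.array([[2.0, 1.0, 7.0, 6.0]])
        s = 3
        out = roi_align(Tensor(feat), box, stride=1, output_size=s).data[0, 0]
        # direct interpolation at each bin center
        for bi in range(s):
            for bj in range(s):
                x = box[0, 0] + (bj + 0.5) / s * (box[0, 2] - box[0, 0]) - 0.5
                y = box[0, 1] + (bi + 0.5) / s * (box[0, 3] - box[0, 1]) - 0.5
                x0, y0 = int(np.floor(x)), int(np.floor(y))
                fx, fy = x - x0, y - y0
                ref = (
                    feat[0, 0, y0, x0] * (1 - fy) * (1 - fx)
                    + feat[0, 0, y0, x0 + 1] * (1 - fy) * fx
                    + feat[0, 0, y0 + 1, x0] * fy * (1 - fx)
                    + feat[0, 0, y0 + 1, x0 + 1] * fy * fx
                )
                assert abs(out[bi, bj] - ref) < 1e-5


class TestProposalsAndLosses:
    def test_proposals_capped_clipped_and_deterministic(self):
        model = Detector(desk_detector_config(), seed=0)
        images, targets, _ = desk_scenes(n=1, image_size=(128, 160))
        with np.errstate(all="ignore"):
            dets1 = model.infer(images[0])
            dets2 = model.infer(images[0])
        pyr = model.forward_features(images[0])
        from trapdet.anchors import generate_anchors as ga
        anchors = np.concatenate(ga(pyr.image_size, pyr, model.config.anchors))
        obj, reg = model.rpn_forward(pyr)
        props = model.select_proposals(
            anchors, obj.data.astype(np.float64), reg.data.astype(np.float64),
            pyr.image_size,
        )
        assert 0 < len(props) <= model.config.rpn.num_proposals
        assert props[:, 0::2].min() >= 0 and props[:, 0::2].max() <= 160
        assert props[:, 1::2].min() >= 0 and props[:, 1::2].max() <= 128
        assert [d.score for d in dets1] == [d.score for d in dets2]

    def test_losses_finite_and_decrease_when_overfitting(self):
        images, targets, _ = desk_scenes(n=1, image_size=(128, 160))
        model = Detector(desk_detector_config(), seed=0)
        hist = train_detector(
            model, images, targets, TrainConfig(iterations=15, lr=0.02), seed=0
        )
        for rec in hist:
            assert all(np.isfinite(v) for v in rec.values())
        assert min(r["total"] for r in hist[5:]) < hist[0]["total"]

    def test_nonfinite_loss_aborts_with_diagnostics(self):
        images, targets, _ = desk_scenes(n=1, image_size=(128, 160))
        model = Detector(desk_detector_config(), seed=0)
        model.roi_head.cls.weight.data[:] = np.nan
        with pytest.raises(TrainingDivergence, match="rcnn_cls"):
            model.compute_losses(images[0], *targets[0], np.random.default_rng(0))

    def test_perfect_regression_targets_give_zero_loss(self):
        anchors = np.array([[0.0, 0.0, 16.0, 16.0]])
        deltas = encode_deltas(anchors, anchors)
        assert np.allclose(deltas, 0.0)


class TestCheckpoint:
    def test_roundtrip_preserves_inference(self, tmp_path):
        model = Detector(desk_detector_config(), seed=0)
        images, _, _ = desk_scenes(n=1, image_size=(128, 160))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, extra={"note": "test"})
        model2 = load_checkpoint(path)
        d1 = model.infer(images[0])
        d2 = model2.infer(images[0])
        assert [(d.class_id, d.score) for d in d1] == [(d.class_id, d.score) for d in d2]

    def test_neck_swap_keeps_shapes(self):
        from dataclasses import replace

        images, _, _ = desk_scenes(n=1, image_size=(128, 160))
        cfg = desk_detector_config()
        m_msr = Detector(cfg, seed=0)
        m_fpn = Detector(replace(cfg, neck="fpn-baseline"), seed=0)
        p1 = m_msr.forward_features(images[0])
        p2 = m_fpn.forward_features(images[0])
        assert [lv.grid for lv in p1.levels] == [lv.grid for lv in p2.levels]
        assert [lv.channels for lv in p1.levels] == [lv.channels for lv in p2.levels]
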