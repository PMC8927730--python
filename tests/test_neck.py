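"""Neck tests: pyramid expansion geometry, fusion residual identity, and
brute-force oracles for the position/channel weighting formulas."""

import numpy as np
import pytest

from trapdet import nn
from trapdet.backbone import BackboneConfig, TinyBackbone, extract_features
from trapdet.neck import (FPNBaselineNeck, FullWeightingParams, MSRConfig,
                          MSRNeck, build_neck, channel_term, full_weighting,
                          local_term)
from trapdet.nn import Tensor


def tiny_pyramid(h=64, w=96, channels=(4, 8, 8, 8), seed=0):
    bb = TinyBackbone(BackboneConfig(channels), rng=np.random.default_rng(seed))
    img = np.random.default_rng(seed + 1).random((h, w, 3)).astype(np.float32)
    return extract_features(img, bb)


def make_neck(oc=8, channels=(4, 8, 8, 8), seed=0, **cfg):
    return MSRNeck(channels, MSRConfig(out_channels=oc, **cfg),
                   rng=np.random.default_rng(seed))


# -- brute-force oracles (independent double-loop implementations) -----


def oracle_local(x, params, normalization="mean"):
    """O(N^2) double loop over positions for the affinity term."""
    c, h, w = x.shape
    wt = params.theta_l.weight.data[:, :, 0, 0]
    bt = params.theta_l.bias.data
    wp = params.phi_l.weight.data[:, :, 0, 0]
    bp = params.phi_l.bias.data
    wg = params.g.weight.data[:, :, 0, 0]
    bg = params.g.bias.data
    pts = x.reshape(c, -1).T  # [N, C]
    n = len(pts)
    theta = pts @ wt.T + bt
    phi = pts @ wp.T + bp
    g = pts @ wg.T + bg
    out = np.zeros_like(g)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j == i:
                continue
            s += float(theta[j] @ phi[i])
        if n > 1:
            a = s / (n - 1) if normalization == "mean" else s
        else:
            a = 0.0
        out[i] = a * g[i]
    return out.T.reshape(c, h, w)


def oracle_channel(x, params):
    c = x.shape[0]
    avg = x.reshape(c, -1).mean(axis=1)
    mx = x.reshape(c, -1).max(axis=1)
    t = params.theta_c.weight.data.T @ avg + params.theta_c.bias.data
    p = params.phi_c.weight.data.T @ mx + params.phi_c.bias.data
    return np.maximum(t, 0) + np.maximum(p, 0)


class TestLocalTerm:
    def test_2x2_identity_maps_closed_form(self):
        # values (1,2,3,4): a_i = mean_{j!=i} x_j * x_i, output a_i * x_i
        params = FullWeightingParams.identity(1)
        x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], dtype=np.float32))
        out = local_term(x, params)
        expected = [3.0, 32 / 3, 21.0, 32.0]  # frozen from the double-loop oracle
        assert np.allclose(out.data.ravel(), expected, atol=1e-5)
        assert np.allclose(
            out.data[0], oracle_local(x.data[0], params), atol=1e-5
        )

    def test_single_position_returns_zero(self):
        params = FullWeightingParams(3, rng=np.random.default_rng(0))
        x = Tensor(np.ones((1, 3, 1, 1), dtype=np.float32))
        assert np.all(local_term(x, params).data == 0.0)

    def test_channel_mismatch_rejected(self):
        params = FullWeightingParams(3)
        with pytest.raises(ValueError):
            local_term(Tensor(np.zeros((1, 2, 4, 4), np.float32)), params)

    @pytest.mark.parametrize("h,w", [(1, 2), (2, 3), (5, 7), (8, 8)])
    def test_matches_brute_force_on_random_maps(self, h, w, rng):
        params = FullWeightingParams(3, rng=np.random.default_rng(5))
        x = rng.normal(size=(1, 3, h, w)).astype(np.float32)
        fast = local_term(Tensor(x), params).data[0]
        slow = oracle_local(x[0], params)
        assert np.max(np.abs(fast - slow)) < 1e-5

    def test_no_normalization_mode(self, rng):
        params = FullWeightingParams(2, rng=np.random.default_rng(3))
        x = rng.normal(size=(1, 2, 3, 4)).astype(np.float32)
        fast = local_term(Tensor(x), params, normalization="none").data[0]
        slow = oracle_local(x[0], params, normalization="none")
        assert np.max(np.abs(fast - slow)) < 1e-4


class TestChannelTerm:
    def test_constant_channels_closed_form(self):
        params = FullWeightingParams.identity(2)
        x = np.stack([np.ones((2, 2)), 3 * np.ones((2, 2))])[None].astype(np.float32)
        w = channel_term(Tensor(x), params)
        assert np.allclose(w.data, [[2.0, 6.0]])

    def test_negative_maps_rectified_to_zero(self):
        params = FullWeightingParams.identity(2)
        for lin in (params.theta_c, params.phi_c):
            lin.weight.data *= -1.0
        x = Tensor(np.abs(np.random.default_rng(0).normal(size=(1, 2, 3, 3))).astype(np.float32))
        assert np.all(channel_term(x, params).data == 0.0)

    def test_position_permutation_invariance(self, rng):
        params = FullWeightingParams(4, rng=np.random.default_rng(2))
        x = rng.normal(size=(1, 4, 3, 5)).astype(np.float32)
        w1 = channel_term(Tensor(x), params).data
        perm = rng.permutation(15)
        xp = x.reshape(1, 4, -1)[:, :, perm].reshape(1, 4, 3, 5)
        w2 = channel_term(Tensor(xp), params).data
        assert np.allclose(w1, w2, atol=1e-6)

    def test_matches_oracle(self, rng):
        params = FullWeightingParams(3, rng=np.random.default_rng(9))
        x = rng.normal(size=(1, 3, 4, 6)).astype(np.float32)
        assert np.allclose(
            channel_term(Tensor(x), params).data[0], oracle_channel(x[0], params),
            atol=1e-5,
        )


class TestFullWeighting:
    def test_alpha_limits_exact(self, rng):
        params = FullWeightingParams(3, rng=np.random.default_rng(4))
        x = Tensor(rng.normal(size=(1, 3, 4, 5)).astype(np.float32))
        w0 = full_weighting(x, params, alpha=0.0).data
        chan = channel_term(x, params).data.reshape(1, 3, 1, 1) * x.data
        assert np.array_equal(w0, chan.astype(np.float32))
        w1 = full_weighting(x, params, alpha=1.0).data
        assert np.array_equal(w1, local_term(x, params).data)

    def test_alpha_half_composition(self):
        params = FullWeightingParams.identity(1)
        x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], dtype=np.float32))
        out = full_weighting(x, params, alpha=0.5).data.ravel()
        # 0.5 * local + 0.5 * (ReLU(2.5) + ReLU(4)) * x, frozen from oracles
        expected = 0.5 * np.array([3.0, 32 / 3, 21.0, 32.0]) + 0.5 * 6.5 * np.array(
            [1.0, 2.0, 3.0, 4.0]
        )
        assert np.allclose(out, expected, atol=1e-5)

    def test_invalid_alpha_rejected(self):
        params = FullWeightingParams.identity(1)
        x = Tensor(np.ones((1, 1, 2, 2), np.float32))
        with pytest.raises(ValueError):
            full_weighting(x, params, alpha=1.5)


class TestPyramidStages:
    def test_sr_component_levels_and_channels(self):
        pyr = tiny_pyramid()
        neck = make_neck()
        sr = neck.sr_component(pyr)
        assert sr.strides == [2, 4, 8, 16, 32, 64]
        assert all(lv.channels == 8 for lv in sr.levels)
        # grid bookkeeping holds at every level (checked by the container)
        assert sr.image_size == pyr.image_size

    def test_sr_requires_four_levels(self):
        pyr = tiny_pyramid()
        neck = make_neck()
        sr = neck.sr_component(pyr)
        with pytest.raises(ValueError):
            neck.sr_component(sr)

    def test_zero_weights_give_zero_sr_pyramid(self):
        pyr = tiny_pyramid()
        neck = make_neck()
        for p in neck.parameters():
            p.data[...] = 0.0
        sr = neck.sr_component(pyr)
        for lv in sr.levels:
            assert np.all(lv.tensor.data == 0.0)

    def test_fusion_residual_identity_with_zero_weights(self):
        # fusion branches are zero-initialized, so full_fusion must return
        # the stride-4..64 levels bit-exactly
        pyr = tiny_pyramid()
        neck = make_neck()
        sr = neck.sr_component(pyr)
        fused = neck.full_fusion(sr)
        assert fused.strides == [4, 8, 16, 32, 64]
        for out, orig in zip(fused.levels, sr.levels[1:]):
            assert np.array_equal(out.tensor.data, orig.tensor.data)

    def test_fusion_projection_consumes_6x_channels(self):
        neck = make_neck(oc=8)
        for proj in neck.fusion:
            assert proj.weight.shape == (8, 48, 1, 1)
        wide = MSRNeck((4, 8, 8, 8), MSRConfig(out_channels=256))
        assert wide.fusion[0].weight.shape == (256, 1536, 1, 1)

    def test_forward_contract_and_determinism(self):
        pyr = tiny_pyramid()
        out1 = make_neck(seed=3)(pyr)
        out2 = make_neck(seed=3)(pyr)
        assert out1.strides == [4, 8, 16, 32, 64]
        assert all(lv.channels == 8 for lv in out1.levels)
        for a, b in zip(out1.levels, out2.levels):
            assert np.array_equal(a.tensor.data, b.tensor.data)

    def test_gradient_reaches_every_parameter(self):
        pyr = tiny_pyramid()
        neck = make_neck(learnable_alpha=True)
        out = neck(pyr)
        loss = out.levels[0].tensor.sum()
        for lv in out.levels[1:]:
            loss = loss + lv.tensor.sum()
        loss.backward()
        for name, p in neck.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.all(np.isfinite(p.grad)), f"non-finite gradient for {name}"

    def test_fpn_baseline_same_contract(self):
        pyr = tiny_pyramid()
        msr = build_neck("msr", (4, 8, 8, 8), MSRConfig(out_channels=8))
        fpn = build_neck("fpn-baseline", (4, 8, 8, 8), MSRConfig(out_channels=8))
        om, of = msr(pyr), fpn(pyr)
        assert om.strides == of.strides
        assert [lv.grid for lv in om.levels] == [lv.grid for lv in of.levels]
        assert [lv.channels for lv in om.levels] == [lv.channels for lv in of.levels]
        with pytest.raises(ValueError):
            build_neck("panet", (4, 8, 8, 8))
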