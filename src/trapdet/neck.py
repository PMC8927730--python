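"""Feature-enhancement neck for tiny, multi-scale, look-alike objects.

Three stages sit between the backbone and the detection heads:

1. **Super-resolution pyramid expansion** — the four backbone levels
   (strides 4..32) are projected to a common width, a finer stride-2 level
   is synthesized by transposed convolution of the stride-4 level (zooming
   in on texture, the way an annotator magnifies a tiny insect), top-down
   fusion and 3x3 smoothing run over the five finest levels, and a coarse
   stride-64 level is appended by stride-2 max pooling: six levels total.

2. **Feature full fusion** — every one of the six levels is bilinearly
   resized to each of the five stride-4..64 target grids; the six same-size
   maps are concatenated (6 x C channels), projected back to C by a 1x1
   convolution, and added residually to the original level of that size.
   Unlike adjacent-level fusion, every output level sees every scale at
   once while preserving translation equivariance.

3. **Feature full weighting** — each level is re-weighted along both
   position and channel:

       W(X) = alpha * pi_L(X) g(X) + (1 - alpha) * pi_C(X) X

   The local term scores each position by its mean affinity to every other
   position, pi_L(x_i) = mean_{j != i} <theta_L(x_j), phi_L(x_i)>, and
   scales the value projection g(x_i) by it (a non-local block restricted
   to a scalar per-position gate).  The channel term pools globally,
   pi_C(X) = ReLU(theta_C(avg(X))) + ReLU(phi_C(max(X))), and gates
   channels (an average+max squeeze-excitation without the sigmoid).

All learnable maps are 1x1 convolutions / linear maps so the whole neck is
differentiable end-to-end and agnostic to grid size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .backbone import FeatureMap, FeaturePyramid, expected_grid
from .nn import Tensor

__all__ = [
    "MSRConfig",
    "FullWeightingParams",
    "local_term",
    "channel_term",
    "full_weighting",
    "MSRNeck",
    "FPNBaselineNeck",
    "build_neck",
]

NECK_STRIDES = (4, 8, 16, 32, 64)


@dataclass(frozen=True)
class MSRConfig:
    """Neck hyperparameters.

    alpha mixes the local (position) and channel terms of the weighting
    stage; with ``learnable_alpha`` it becomes a trained scalar squashed
    through a sigmoid.  ``local_normalization`` controls whether the
    pairwise affinity sum is averaged over the N-1 other positions
    ("mean", keeps activations scale-stable across grid sizes) or left
    raw ("none").  ``channel_gate`` optionally squashes the channel
    weights through a sigmoid instead of using the rectified sum
    literally.
    """

    out_channels: int = 256
    smooth_kernel: int = 3
    deconv_kernel: int = 4
    deconv_stride: int = 2
    alpha: float = 0.5
    learnable_alpha: bool = False
    local_normalization: str = "mean"  # mean | none
    channel_gate: str = "literal"  # literal | sigmoid

    def __post_init__(self) -> None:
        if self.out_channels <= 0:
            raise ValueError("out_channels must be positive")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.local_normalization not in ("mean", "none"):
            raise ValueError("local_normalization must be 'mean' or 'none'")
        if self.channel_gate not in ("literal", "sigmoid"):
            raise ValueError("channel_gate must be 'literal' or 'sigmoid'")


class FullWeightingParams(nn.Module):
    """Learnable maps of the full-weighting stage.

    ``theta_l``, ``phi_l``, ``g`` are per-position 1x1 projections on C
    channels; ``theta_c``, ``phi_c`` act on globally pooled C-vectors.
    """

    def __init__(self, channels: int, rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        c = channels
        self.channels = c
        # near-neutral start: the local term begins close to zero and the
        # channel weights close to one, so W(X) ~ (1 - alpha) * X at init
        # and the weighting stage learns how far to depart from identity
        self.theta_l = nn.Conv2d(c, c, 1, rng=rng, init="gaussian", init_std=0.01)
        self.phi_l = nn.Conv2d(c, c, 1, rng=rng, init="gaussian", init_std=0.01)
        self.g = nn.Conv2d(c, c, 1, rng=rng, init="gaussian", init_std=0.01)
        self.theta_c = nn.Linear(c, c, rng=rng, init="gaussian", init_std=0.01)
        self.phi_c = nn.Linear(c, c, rng=rng, init="gaussian", init_std=0.01)
        self.theta_c.bias.data[:] = 0.5
        self.phi_c.bias.data[:] = 0.5

    @classmethod
    def identity(cls, channels: int) -> "FullWeightingParams":
        """All five maps set to the identity (for closed-form checks)."""
        p = cls(channels)
        eye4 = np.eye(channels, dtype=np.float32)[:, :, None, None]
        for conv in (p.theta_l, p.phi_l, p.g):
            conv.weight.data = eye4.copy()
            conv.bias.data[:] = 0.0
        for lin in (p.theta_c, p.phi_c):
            lin.weight.data = np.eye(channels, dtype=np.float32)
            lin.bias.data[:] = 0.0
        return p


def _check_channels(x: Tensor, params: FullWeightingParams) -> None:
    if x.shape[1] != params.channels:
        raise ValueError(
            f"feature map has {x.shape[1]} channels, params expect {params.channels}"
        )


def local_term(
    x: Tensor, params: FullWeightingParams, normalization: str = "mean"
) -> Tensor:
    """Position-affinity term: a_i * g(x_i) with
    a_i = mean_{j != i} <theta_L(x_j), phi_L(x_i)>.

    Evaluated in O(N·C) by precomputing the sum of theta over positions:
    sum_{j != i} theta(x_j) = S - theta(x_i).  A single-position map has an
    empty sum and returns zeros.
    """
    _check_channels(x, params)
    _, _, h, w = x.shape
    n = h * w
    if n == 1:
        return x * 0.0
    theta = params.theta_l(x)
    phi = params.phi_l(x)
    g = params.g(x)
    s = theta.sum(axis=(2, 3), keepdims=True)
    affinity = ((s - theta) * phi).sum(axis=1, keepdims=True)
    if normalization == "mean":
        affinity = affinity * (1.0 / (n - 1))
    return affinity * g


def channel_term(
    x: Tensor, params: FullWeightingParams, gate: str = "literal"
) -> Tensor:
    """Channel weights ReLU(theta_C(avg(X))) + ReLU(phi_C(max(X))) -> [1, C]."""
    _check_channels(x, params)
    avg = nn.global_avg_pool(x)
    mx = nn.global_max_pool(x)
    w = nn.relu(params.theta_c(avg)) + nn.relu(params.phi_c(mx))
    if gate == "sigmoid":
        w = nn.sigmoid(w)
    return w


def full_weighting(
    x: Tensor,
    params: FullWeightingParams,
    alpha: float | Tensor = 0.5,
    normalization: str = "mean",
    gate: str = "literal",
) -> Tensor:
    """alpha * local term + (1 - alpha) * channel-gated features."""
    if not isinstance(alpha, Tensor) and not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    loc = local_term(x, params, normalization)
    wc = channel_term(x, params, gate)
    c = x.shape[1]
    chan = wc.reshape(1, c, 1, 1) * x
    one_minus = (1.0 - alpha) if not isinstance(alpha, Tensor) else (1.0 - alpha)
    return loc * alpha + chan * one_minus


class MSRNeck(nn.Module):
    """The three-stage enhancement neck; consumes a 4-level backbone
    pyramid (strides 4..32), emits 5 levels at strides 4..64."""

    def __init__(
        self,
        in_channels: tuple[int, int, int, int],
        config: MSRConfig = MSRConfig(),
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        oc = config.out_channels
        self.laterals = [nn.Conv2d(c, oc, 1, rng=rng) for c in in_channels]
        self.deconv = nn.ConvTranspose2d(
            oc, oc, config.deconv_kernel, config.deconv_stride,
            padding=(config.deconv_kernel - config.deconv_stride) // 2, rng=rng,
        )
        k = config.smooth_kernel
        self.smooth = [
            nn.Conv2d(oc, oc, k, padding=k // 2, rng=rng) for _ in range(5)
        ]
        # residual fusion branches start at zero so the neck begins as a
        # plain pyramid and learns how much cross-scale mixing to add
        self.fusion = [nn.Conv2d(6 * oc, oc, 1, init="zeros") for _ in range(5)]
        self.weighting = FullWeightingParams(oc, rng=rng)
        if config.learnable_alpha:
            # alpha = sigmoid(raw); raw=0 gives the 0.5 default
            self._alpha_raw = Tensor(np.float32(0.0), requires_grad=True)
        else:
            self._alpha_raw = None

    @property
    def alpha(self) -> float | Tensor:
        if self._alpha_raw is None:
            return self.config.alpha
        return nn.sigmoid(self._alpha_raw)

    # -- stage 1: super-resolution pyramid expansion -------------------

    def sr_component(self, pyramid: FeaturePyramid) -> FeaturePyramid:
        if len(pyramid) != 4 or pyramid.strides != [4, 8, 16, 32]:
            raise ValueError(
                f"expected 4 levels at strides 4..32, got {pyramid.strides}"
            )
        img = pyramid.image_size
        laterals = [
            lat(lv.tensor) for lat, lv in zip(self.laterals, pyramid.levels)
        ]
        p2 = self.deconv(laterals[0], output_size=expected_grid(img, 2))
        fine = [p2] + laterals  # strides 2, 4, 8, 16, 32
        strides = [2, 4, 8, 16, 32]
        # top-down: add each level (resized) into the one below
        for i in range(len(fine) - 2, -1, -1):
            up = nn.bilinear_resize(
                fine[i + 1], fine[i].shape[2], fine[i].shape[3]
            )
            fine[i] = fine[i] + up
        smoothed = [conv(t) for conv, t in zip(self.smooth, fine)]
        top = nn.max_pool_stride2(smoothed[-1])
        levels = [
            FeatureMap(t, s) for t, s in zip(smoothed + [top], strides + [64])
        ]
        return FeaturePyramid(levels, img)

    # -- stage 2: feature full fusion ----------------------------------

    def full_fusion(self, sr: FeaturePyramid) -> FeaturePyramid:
        if len(sr) != 6 or sr.strides != [2, 4, 8, 16, 32, 64]:
            raise ValueError(f"expected 6 levels at strides 2..64, got {sr.strides}")
        oc = self.config.out_channels
        img = sr.image_size
        out_levels = []
        for t_idx, stride in enumerate(NECK_STRIDES):
            gh, gw = expected_grid(img, stride)
            proj = self.fusion[t_idx]
            # 1x1 projection of the 6C-channel concatenation, evaluated
            # blockwise (one GEMM per source level) to avoid materializing
            # the concatenated map
            acc = None
            for k, lv in enumerate(sr.levels):
                resized = nn.bilinear_resize(lv.tensor, gh, gw)
                w_block = proj.weight[:, k * oc : (k + 1) * oc, :, :]
                piece = nn.functional.conv2d(resized, w_block)
                acc = piece if acc is None else acc + piece
            acc = acc + proj.bias.reshape(1, oc, 1, 1)
            base = sr.levels[t_idx + 1].tensor  # the stride-4..64 original
            out_levels.append(FeatureMap(base + acc, stride))
        return FeaturePyramid(out_levels, img)

    # -- stage 3: feature full weighting -------------------------------

    def full_weighting_stage(self, pyr: FeaturePyramid) -> FeaturePyramid:
        cfg = self.config
        levels = [
            FeatureMap(
                full_weighting(
                    lv.tensor,
                    self.weighting,
                    self.alpha,
                    cfg.local_normalization,
                    cfg.channel_gate,
                ),
                lv.stride,
            )
            for lv in pyr.levels
        ]
        return FeaturePyramid(levels, pyr.image_size)

    def __call__(self, pyramid: FeaturePyramid) -> FeaturePyramid:
        return self.full_weighting_stage(self.full_fusion(self.sr_component(pyramid)))


class FPNBaselineNeck(nn.Module):
    """Standard top-down pyramid (laterals + upsample-add + 3x3 smooth,
    extra stride-64 level by stride-2 subsampling); same 5-level contract
    as :class:`MSRNeck` so the two are swappable by config."""

    def __init__(
        self,
        in_channels: tuple[int, int, int, int],
        config: MSRConfig = MSRConfig(),
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        oc = config.out_channels
        self.laterals = [nn.Conv2d(c, oc, 1, rng=rng) for c in in_channels]
        k = config.smooth_kernel
        self.smooth = [nn.Conv2d(oc, oc, k, padding=k // 2, rng=rng) for _ in range(4)]

    def __call__(self, pyramid: FeaturePyramid) -> FeaturePyramid:
        if len(pyramid) != 4 or pyramid.strides != [4, 8, 16, 32]:
            raise ValueError(f"expected 4 levels at strides 4..32, got {pyramid.strides}")
        laterals = [lat(lv.tensor) for lat, lv in zip(self.laterals, pyramid.levels)]
        for i in range(len(laterals) - 2, -1, -1):
            up = nn.bilinear_resize(laterals[i + 1], laterals[i].shape[2], laterals[i].shape[3])
            laterals[i] = laterals[i] + up
        smoothed = [conv(t) for conv, t in zip(self.smooth, laterals)]
        top = nn.max_pool_stride2(smoothed[-1])
        levels = [FeatureMap(t, s) for t, s in zip(smoothed + [top], [4, 8, 16, 32, 64])]
        return FeaturePyramid(levels, pyramid.image_size)


def build_neck(
    kind: str,
    in_channels: tuple[int, int, int, int],
    config: MSRConfig = MSRConfig(),
    rng: Optional[np.random.Generator] = None,
):
    """Neck factory: ``msr`` | ``fpn-baseline``."""
    if kind == "msr":
        return MSRNeck(in_channels, config, rng)
    if kind == "fpn-baseline":
        return FPNBaselineNeck(in_channels, config, rng)
    raise ValueError(f"unknown neck kind {kind!r}")
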