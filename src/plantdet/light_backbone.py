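"""Residual feature extractor with optional depthwise-separable blocks.

The light bottleneck replaces the 3x3 full convolution of a standard
bottleneck with a 3x3 depthwise convolution (one filter per channel),
keeping the 1x1 compression / 1x1 pointwise expansion and the residual
connection.  Blocks assemble into a ResNet-50-layout extractor whose
first three stages produce stride-16 features (600 -> 38); the fourth
stage is returned separately for use as the RoI head.  A Split SAM gate
can be appended to every block of selected stages.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .split_sam import SplitSAM, SplitSAMParams

__all__ = ["LightBottleneckSpec", "BackboneSpec", "Bottleneck", "Backbone",
           "bottleneck_param_count", "build_backbone", "EXPANSION"]

EXPANSION = 4


@dataclass(frozen=True)
class LightBottleneckSpec:
    in_channels: int
    mid_channels: int
    out_channels: int
    stride: int = 1
    use_sam: bool = False
    sam_kernel: int = 7

    def __post_init__(self):
        if self.out_channels != EXPANSION * self.mid_channels:
            raise ValueError(
                f"out_channels must be {EXPANSION} x mid_channels, got "
                f"{self.out_channels} vs {self.mid_channels}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")

    @property
    def has_projection(self) -> bool:
        return self.stride != 1 or self.in_channels != self.out_channels


def bottleneck_param_count(spec: LightBottleneckSpec, light: bool) -> dict:
    """Closed-form learnable-parameter census of one bottleneck block.

    Convolutions carry no bias; every normalized channel contributes two
    affine parameters.  Returns conv / norm / sam components and total.
    """
    cin, mid, cout = spec.in_channels, spec.mid_channels, spec.out_channels
    conv = cin * mid  # 1x1 compression
    conv += (mid * 9) if light else (mid * mid * 9)  # 3x3 (depthwise if light)
    conv += mid * cout  # 1x1 pointwise expansion
    norm = 2 * mid + 2 * mid + 2 * cout
    if spec.has_projection:
        conv += cin * cout
        norm += 2 * cout
    sam = (2 * spec.sam_kernel ** 2 + 1) if spec.use_sam else 0
    return {"conv": conv, "norm": norm, "sam": sam, "total": conv + norm + sam}


class Bottleneck(nn.Module):
    def __init__(self, spec: LightBottleneckSpec, light: bool = True, rng=None):
        super().__init__()
        self.spec = spec
        self.light = light
        rng = rng or np.random.default_rng(0)
        cin, mid, cout = spec.in_channels, spec.mid_channels, spec.out_channels
        self.conv1 = nn.Conv2d(cin, mid, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        groups = mid if light else 1
        self.conv2 = nn.Conv2d(mid, mid, 3, stride=spec.stride, padding=1,
                               groups=groups, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, cout, 1, rng=rng)
        self.bn3 = nn.BatchNorm2d(cout)
        if spec.has_projection:
            self.down_conv = nn.Conv2d(cin, cout, 1, stride=spec.stride, rng=rng)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down_conv = None
        if spec.use_sam:
            self.sam = SplitSAM(SplitSAMParams(conv_kernel=spec.sam_kernel),
                                rng=rng)
        else:
            self.sam = None

    def forward(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"block expects {self.spec.in_channels} channels, got {x.shape[1]}")
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        shortcut = self.down_bn(self.down_conv(x)) if self.down_conv else x
        out = (out + shortcut).relu()
        if self.sam is not None:
            out = self.sam(out)
        return out


@dataclass(frozen=True)
class BackboneSpec:
    stage_block_counts: tuple = (3, 4, 6, 3)
    stage_mid_channels: tuple = (64, 128, 256, 512)
    stem_channels: int = 64
    feature_stride: int = 16
    light: bool = True
    sam_stages: tuple = (False, False, False, False)
    sam_kernel: int = 7

    def __post_init__(self):
        n = len(self.stage_block_counts)
        if n != 4 or len(self.stage_mid_channels) != n or len(self.sam_stages) != n:
            raise ValueError("backbone spec requires 4 aligned stage lists")
        if any(b < 1 for b in self.stage_block_counts):
            raise ValueError("every stage needs at least one block")


def _make_stage(cin, mid, n_blocks, stride, light, use_sam, sam_kernel, rng):
    blocks = []
    for b in range(n_blocks):
        spec = LightBottleneckSpec(cin if b == 0 else EXPANSION * mid, mid,
                                   EXPANSION * mid,
                                   stride=stride if b == 0 else 1,
                                   use_sam=use_sam, sam_kernel=sam_kernel)
        blocks.append(Bottleneck(spec, light=light, rng=rng))
    return nn.Sequential(*blocks)


class Backbone(nn.Module):
    """Stem + stages 1-3 (stride 16) with stage 4 kept aside as RoI head."""

    def __init__(self, spec: BackboneSpec = BackboneSpec(), seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        sc = spec.stem_channels
        self.stem_conv = nn.Conv2d(3, sc, 7, stride=2, padding=3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(sc)
        self.pool = nn.MaxPool2d(3, stride=2, padding=1)
        mids = spec.stage_mid_channels
        self.stage1 = _make_stage(sc, mids[0], spec.stage_block_counts[0], 1,
                                  spec.light, spec.sam_stages[0], spec.sam_kernel, rng)
        self.stage2 = _make_stage(EXPANSION * mids[0], mids[1],
                                  spec.stage_block_counts[1], 2, spec.light,
                                  spec.sam_stages[1], spec.sam_kernel, rng)
        self.stage3 = _make_stage(EXPANSION * mids[1], mids[2],
                                  spec.stage_block_counts[2], 2, spec.light,
                                  spec.sam_stages[2], spec.sam_kernel, rng)
        # stage 4 runs on pooled RoI features, so its first block keeps stride 1
        self.head = _make_stage(EXPANSION * mids[2], mids[3],
                                spec.stage_block_counts[3], 1, spec.light,
                                spec.sam_stages[3], spec.sam_kernel, rng)
        self.out_channels = EXPANSION * mids[2]
        self.head_out_channels = EXPANSION * mids[3]

    def forward(self, x):
        x = self.stem_bn(self.stem_conv(x)).relu()
        x = self.pool(x)
        x = self.stage1(x)
        x = self.stage2(x)
        x = self.stage3(x)
        return x

    def extractor_params(self) -> int:
        head = self.head.num_params()
        return self.num_params() - head


def build_backbone(spec: BackboneSpec = BackboneSpec(), seed: int = 0) -> Backbone:
    """Instantiate the feature extractor (callable) with its RoI-head stage."""
    return Backbone(spec, seed=seed)
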