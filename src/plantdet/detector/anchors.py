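"""Anchor generation for the region proposal network.

Anchors tile the feature map at one per cell center per (ratio, scale)
pair.  The base side is scale x feat_stride (so scales 8/16/32 at stride
16 give 128/256/512 px squares at ratio 1); ratio r rescales to
height/width = r at constant area.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnchorSpec", "generate_anchors", "base_anchors"]


@dataclass(frozen=True)
class AnchorSpec:
    ratios: tuple = (0.5, 1.0, 2.0)
    scales: tuple = (8, 16, 32)
    feat_stride: int = 16

    @property
    def anchors_per_cell(self) -> int:
        return len(self.ratios) * len(self.scales)


def base_anchors(spec: AnchorSpec) -> np.ndarray:
    """(A, 4) anchors centered at the origin."""
    out = []
    for r in spec.ratios:
        for s in spec.scales:
            base = s * spec.feat_stride
            w = base / np.sqrt(r)
            h = base * np.sqrt(r)
            out.append([-w / 2, -h / 2, w / 2, h / 2])
    return np.array(out, dtype=np.float64)


def generate_anchors(spec: AnchorSpec, map_h: int, map_w: int) -> np.ndarray:
    """All anchors for an H x W feature map, shape (H*W*A, 4), input pixels."""
    if map_h < 1 or map_w < 1:
        raise ValueError("feature map dimensions must be >= 1")
    base = base_anchors(spec)
    stride = spec.feat_stride
    cx = (np.arange(map_w) + 0.5) * stride
    cy = (np.arange(map_h) + 0.5) * stride
    shift_x, shift_y = np.meshgrid(cx, cy)
    shifts = np.stack([shift_x.ravel(), shift_y.ravel(),
                       shift_x.ravel(), shift_y.ravel()], axis=1)
    anchors = shifts[:, None, :] + base[None, :, :]
    return anchors.reshape(-1, 4)
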