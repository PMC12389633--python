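"""Grouped spatial attention (Split SAM).

The channel axis is split into G contiguous groups; each group is gated
by a sigmoid attention map obtained from its channel-wise max/avg pooled
pair passed through a shared 7x7 convolution (2 -> 1 channels, padding
preserves H x W).  G defaults to 1.  Functional NumPy entry points mirror
the trainable :class:`SplitSAM` module one-to-one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["SplitSAMParams", "PooledPair", "split_channels", "channel_pool",
           "attention_map", "apply_split_sam", "SplitSAM", "init_sam_weights"]


@dataclass(frozen=True)
class SplitSAMParams:
    groups: int = 1
    conv_kernel: int = 7

    def __post_init__(self):
        if self.groups < 1:
            raise ValueError(f"groups must be >= 1, got {self.groups}")
        if self.conv_kernel % 2 == 0 or self.conv_kernel < 1:
            raise ValueError(f"conv_kernel must be odd, got {self.conv_kernel}")


@dataclass(frozen=True)
class PooledPair:
    f_max: np.ndarray  # (B, 1, H, W)
    f_avg: np.ndarray  # (B, 1, H, W)

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.f_max, self.f_avg], axis=1)


def _check_rank4(x):
    x = np.asarray(x)
    if x.ndim != 4:
        raise ValueError(f"expected a B x C x H x W tensor, got shape {x.shape}")
    return x


def split_channels(x: np.ndarray, g: int) -> list[np.ndarray]:
    """Contiguous channel split into g groups of C/g channels each."""
    x = _check_rank4(x)
    c = x.shape[1]
    if c % g != 0:
        raise ValueError(f"channel count {c} not divisible by groups {g}")
    return list(np.split(x, g, axis=1))


def channel_pool(xg: np.ndarray) -> PooledPair:
    """Max and mean ACROSS channels, keeping spatial dimensions."""
    xg = _check_rank4(xg)
    return PooledPair(
        f_max=xg.max(axis=1, keepdims=True),
        f_avg=xg.mean(axis=1, keepdims=True),
    )


def attention_map(fg: PooledPair | np.ndarray, weight: np.ndarray,
                  bias: np.ndarray | None = None) -> np.ndarray:
    """Sigmoid of one KxK convolution over the pooled pair: values in (0,1)."""
    cat = fg.concatenated if isinstance(fg, PooledPair) else _check_rank4(fg)
    if cat.shape[1] != 2:
        raise ValueError(f"pooled pair must have 2 channels, got {cat.shape[1]}")
    weight = np.asarray(weight, dtype=np.float32)
    if weight.ndim != 4 or weight.shape[:2] != (1, 2) or weight.shape[2] != weight.shape[3]:
        raise ValueError(f"attention conv weight must be (1, 2, k, k), got {weight.shape}")
    k = weight.shape[2]
    with nn.no_grad():
        out = F.conv2d(Tensor(cat), Tensor(weight),
                       Tensor(bias) if bias is not None else None,
                       stride=1, padding=k // 2)
        return out.sigmoid().numpy()


def apply_split_sam(x: np.ndarray, params: SplitSAMParams, weight: np.ndarray,
                    bias: np.ndarray | None = None) -> np.ndarray:
    """Gate each channel group by its attention map and re-concatenate."""
    groups = split_channels(x, params.groups)
    gated = []
    for xg in groups:
        m = attention_map(channel_pool(xg), weight, bias)
        gated.append(xg * m)
    return np.concatenate(gated, axis=1)


def init_sam_weights(kernel: int = 7, seed: int = 0):
    """Kaiming-style (fan-in) initialized 2->1 conv weights and zero bias."""
    rng = np.random.default_rng(seed)
    fan_in = 2 * kernel * kernel
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(1, 2, kernel, kernel))
    return w.astype(np.float32), np.zeros(1, dtype=np.float32)


class SplitSAM(nn.Module):
    """Trainable Split SAM layer; one weight set shared across groups."""

    def __init__(self, params: SplitSAMParams = SplitSAMParams(), rng=None):
        super().__init__()
        self.params = params
        k = params.conv_kernel
        self.conv = nn.Conv2d(2, 1, k, stride=1, padding=k // 2, bias=True,
                              rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        g = self.params.groups
        c = x.shape[1]
        if c % g != 0:
            raise ValueError(f"channel count {c} not divisible by groups {g}")
        cg = c // g
        outs = []
        for i in range(g):
            xg = x[:, i * cg:(i + 1) * cg]
            f_max = xg.max(axis=1, keepdims=True)
            f_avg = xg.mean(axis=1, keepdims=True)
            m = self.conv(nn.concat([f_max, f_avg], axis=1)).sigmoid()
            outs.append(xg * m)
        return outs[0] if g == 1 else nn.concat(outs, axis=1)
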