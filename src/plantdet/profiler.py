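"""Model complexity accounting and edge-performance scaling arithmetic.

Parameter counts are an exact census by layer type.  MAC counts come
from one traced forward pass (every module records its last in/out
shapes): convolution contributes k^2 * Cin/groups * Cout * Hout * Wout
per batch element, a linear layer in * out per row.  FLOPs are reported
as 2 x MACs, with the convention recorded in the report.

The edge-performance model is pure arithmetic over a locally measured
frame rate, a device frame rate and a structural complexity factor r:
speed_up1 = fps_device / fps_base, speed_up2 = speed_up1 / r and
fps_simulated = fps_base * speed_up2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor

__all__ = ["ComplexityReport", "EdgePerf", "count_params", "count_macs",
           "profile_model", "profile_detector", "speedup_factor",
           "structural_speedup", "simulated_fps"]


@dataclass
class ComplexityReport:
    total_params: int = 0
    conv_params: int = 0
    norm_params: int = 0
    linear_params: int = 0
    macs: int = 0
    input_size: tuple | None = None
    flops_convention: str = "flops = 2 * macs"

    @property
    def flops(self) -> int:
        return 2 * self.macs

    def merged(self, other: "ComplexityReport") -> "ComplexityReport":
        return ComplexityReport(
            total_params=self.total_params + other.total_params,
            conv_params=self.conv_params + other.conv_params,
            norm_params=self.norm_params + other.norm_params,
            linear_params=self.linear_params + other.linear_params,
            macs=self.macs + other.macs,
            input_size=self.input_size or other.input_size,
        )


def _leaf_modules(model: nn.Module):
    for name, mod in model.named_modules():
        if isinstance(mod, (nn.Conv2d, nn.BatchNorm2d, nn.Linear)):
            yield name, mod


def count_params(model: nn.Module) -> ComplexityReport:
    """Exact learnable-parameter census by layer type."""
    rep = ComplexityReport()
    for _name, mod in _leaf_modules(model):
        n = sum(p.size for p in mod._params.values())
        if isinstance(mod, nn.Conv2d):
            rep.conv_params += n
        elif isinstance(mod, nn.BatchNorm2d):
            rep.norm_params += n
        else:
            rep.linear_params += n
    rep.total_params = rep.conv_params + rep.norm_params + rep.linear_params
    return rep


def _module_macs(name: str, mod: nn.Module) -> int:
    if mod.last_out_shape is None:
        raise ValueError(
            f"layer {name!r} has no recorded activation shapes; run a traced "
            f"forward pass at the profiling input size first")
    if isinstance(mod, nn.Conv2d):
        n, cout, ho, wo = mod.last_out_shape
        cin_g = mod.in_channels // mod.groups
        return mod.kernel_size ** 2 * cin_g * cout * ho * wo * n
    if isinstance(mod, nn.Linear):
        rows = int(np.prod(mod.last_in_shape[:-1]))
        return rows * mod.in_features * mod.out_features
    return 0


def count_macs(model: nn.Module, input_size=None, trace_fn=None) -> ComplexityReport:
    """MAC count from a traced forward; flops = 2 * macs.

    Either pass ``input_size`` (square RGB input, model called directly)
    or a ``trace_fn(model)`` that exercises every profiled layer.
    """
    model.eval()
    if trace_fn is not None:
        with nn.no_grad():
            trace_fn(model)
    elif input_size is not None:
        x = Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
        with nn.no_grad():
            model(x)
    rep = count_params(model)
    macs = 0
    for name, mod in _leaf_modules(model):
        if isinstance(mod, (nn.Conv2d, nn.Linear)):
            macs += _module_macs(name, mod)
    rep.macs = macs
    rep.input_size = (input_size, input_size) if input_size else None
    return rep


def profile_model(model: nn.Module, input_size: int) -> ComplexityReport:
    from .light_backbone import Backbone

    if isinstance(model, Backbone):
        # the fourth stage is the RoI head; trace it on the stage-3 output
        def trace(m):
            x = Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
            m.head(m(x))

        rep = count_macs(model, trace_fn=trace)
        rep.input_size = (input_size, input_size)
        return rep
    return count_macs(model, input_size=input_size)


def profile_detector(model, input_size: int | None = None,
                     proposals: int = 300) -> ComplexityReport:
    """Full detector complexity at a given proposal count.

    Traces extractor + RPN on a blank input and the RoI head on
    ``proposals`` full-image boxes, so head MACs scale with the count.
    """
    size = input_size or model.input_size

    def trace(m):
        feats = m.extract(m.normalize_image(
            np.zeros((size, size, 3), dtype=np.uint8)))
        m.rpn_forward(feats)
        rois = np.tile([0.0, 0.0, float(size), float(size)], (proposals, 1))
        m.roi_forward(feats, rois)

    rep = count_macs(model, trace_fn=trace)
    rep.input_size = (size, size)
    return rep


# ------------------------------------------------------- edge-perf scaling

def speedup_factor(fps_device: float, fps_base: float) -> float:
    """Ratio of device frame rate to locally measured frame rate."""
    if fps_base <= 0:
        raise ValueError(f"fps_base must be > 0, got {fps_base}")
    return fps_device / fps_base


def structural_speedup(speed_up1: float, r: float) -> float:
    """Scale a measured speed-up by the structural complexity factor r."""
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    return speed_up1 / r


def simulated_fps(fps_base: float, speed_up2: float) -> float:
    if fps_base <= 0 or speed_up2 <= 0:
        raise ValueError("fps_base and speed_up2 must be > 0")
    return fps_base * speed_up2


@dataclass
class EdgePerf:
    """Edge-performance estimate with the reference constants as defaults."""

    fps_base: float = 0.08
    fps_device: float = 0.5
    r: float = 0.35

    def __post_init__(self):
        if self.fps_base <= 0:
            raise ValueError("fps_base must be > 0")
        if not 0 < self.r <= 1:
            raise ValueError("r must be in (0, 1]")

    @property
    def t_base(self) -> float:
        return 1.0 / self.fps_base

    @property
    def speed_up1(self) -> float:
        return speedup_factor(self.fps_device, self.fps_base)

    @property
    def speed_up2(self) -> float:
        return structural_speedup(self.speed_up1, self.r)

    @property
    def fps_simulated(self) -> float:
        return simulated_fps(self.fps_base, self.speed_up2)

    def report(self) -> dict:
        return {
            "fps_base": self.fps_base,
            "t_base_s": self.t_base,
            "fps_device": self.fps_device,
            "r": self.r,
            "speed_up1": self.speed_up1,
            "speed_up2": self.speed_up2,
            "fps_simulated": self.fps_simulated,
        }
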