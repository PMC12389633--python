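"""Two-stage detector: RPN over stride-16 features + RoI-pooled head.

The feature extractor is the (optionally light / SAM-gated) residual
backbone; its fourth stage runs on RoI-pooled features before global
average pooling and the parallel classification / box-regression linears.
Box regression is class-agnostic; classification includes a background
class at index 0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..light_backbone import Backbone, BackboneSpec
from ..nn import functional as F
from ..nn.tensor import Tensor
from .anchors import AnchorSpec, generate_anchors
from .boxes import (clip_boxes, decode_boxes, letterbox_image, nms,
                    unletterbox_boxes)

__all__ = ["RPNSpec", "Detection", "FasterRCNN", "propose"]


@dataclass(frozen=True)
class RPNSpec:
    nms_iou: float = 0.7
    pre_nms_top_n: int = 3000
    post_nms_top_n: int = 300
    min_size: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.nms_iou < 1.0:
            raise ValueError(f"nms_iou must be in (0,1), got {self.nms_iou}")


@dataclass(frozen=True)
class Detection:
    box: tuple  # (x1, y1, x2, y2), 0-based half-open, input-pixel units
    label: str
    score: float

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate detection box {self.box}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score outside [0,1]: {self.score}")


def propose(objectness: np.ndarray, box_deltas: np.ndarray,
            anchors: np.ndarray, spec: RPNSpec, image_size: int):
    """Decode RPN outputs into scored proposals.

    objectness: (N,) scores; box_deltas: (N, 4); anchors: (N, 4).
    Returns (boxes (M,4), scores (M,)) after clipping, degenerate-box
    removal, top-k preselection and NMS.
    """
    objectness = np.asarray(objectness, dtype=np.float64).ravel()
    box_deltas = np.asarray(box_deltas, dtype=np.float64).reshape(-1, 4)
    if not (len(objectness) == len(box_deltas) == len(anchors)):
        raise ValueError("objectness, deltas and anchors must align")
    boxes = clip_boxes(decode_boxes(anchors, box_deltas), image_size, image_size)
    wh = boxes[:, 2:] - boxes[:, :2]
    valid = (wh >= spec.min_size).all(axis=1)
    boxes, scores = boxes[valid], objectness[valid]
    if len(boxes) > spec.pre_nms_top_n:
        top = np.argsort(-scores, kind="stable")[:spec.pre_nms_top_n]
        boxes, scores = boxes[top], scores[top]
    keep = nms(boxes, scores, spec.nms_iou)[:spec.post_nms_top_n]
    return boxes[keep], scores[keep]


class FasterRCNN(nn.Module):
    def __init__(self, class_names, backbone_spec: BackboneSpec = BackboneSpec(),
                 anchor_spec: AnchorSpec = AnchorSpec(),
                 rpn_spec: RPNSpec = RPNSpec(), input_size: int = 600,
                 rpn_channels: int = 256, roi_pool_size: int = 7,
                 seed: int = 0):
        super().__init__()
        self.class_names = list(class_names)
        self.num_classes = len(self.class_names)
        self.anchor_spec = anchor_spec
        self.rpn_spec = rpn_spec
        self.input_size = input_size
        self.roi_pool_size = roi_pool_size
        rng = np.random.default_rng(seed + 1)
        self.backbone = Backbone(backbone_spec, seed=seed)
        c3 = self.backbone.out_channels
        a = anchor_spec.anchors_per_cell
        self.rpn_conv = nn.Conv2d(c3, rpn_channels, 3, padding=1, rng=rng)
        self.rpn_bn = nn.BatchNorm2d(rpn_channels)
        self.rpn_obj = nn.Conv2d(rpn_channels, a, 1, bias=True, rng=rng)
        self.rpn_reg = nn.Conv2d(rpn_channels, 4 * a, 1, bias=True, rng=rng)
        c4 = self.backbone.head_out_channels
        self.cls_head = nn.Linear(c4, self.num_classes + 1, rng=rng)
        self.reg_head = nn.Linear(c4, 4, rng=rng)
        # small initial regression weights keep early proposals near anchors
        self.rpn_reg.weight.data *= 0.1
        self.reg_head.weight.data *= 0.1
        # small-batch training: normalize by current-input stats at eval too
        for _name, mod in self.named_modules():
            if isinstance(mod, nn.BatchNorm2d):
                mod.use_batch_stats_in_eval = True

    # ----------------------------------------------------------- internals
    @staticmethod
    def normalize_image(img: np.ndarray) -> Tensor:
        arr = np.asarray(img, dtype=np.float32) / 127.5 - 1.0
        return Tensor(arr.transpose(2, 0, 1)[None])

    def extract(self, x: Tensor) -> Tensor:
        return self.backbone(x)

    def rpn_forward(self, features: Tensor):
        """Returns flattened (objectness logits (N,), deltas (N,4)) tensors."""
        h = self.rpn_bn(self.rpn_conv(features)).relu()
        obj = self.rpn_obj(h)   # (1, A, Hf, Wf)
        reg = self.rpn_reg(h)   # (1, 4A, Hf, Wf)
        a = self.anchor_spec.anchors_per_cell
        _, _, hf, wf = obj.shape
        # to (Hf*Wf*A,) and (Hf*Wf*A, 4), matching generate_anchors order
        obj_flat = obj.transpose((0, 2, 3, 1)).reshape(hf * wf * a)
        reg_flat = reg.reshape(a, 4, hf, wf).transpose((2, 3, 0, 1)).reshape(hf * wf * a, 4)
        return obj_flat, reg_flat

    def anchors_for(self, features) -> np.ndarray:
        _, _, hf, wf = features.shape
        return generate_anchors(self.anchor_spec, hf, wf)

    def roi_forward(self, features: Tensor, rois: np.ndarray):
        """Classification logits and box deltas for each RoI."""
        scale = 1.0 / self.anchor_spec.feat_stride
        pooled = F.roi_max_pool(features, rois, self.roi_pool_size, scale)
        h = self.backbone.head(pooled)
        h = h.mean(axis=(2, 3))
        return self.cls_head(h), self.reg_head(h)

    # ------------------------------------------------------------ inference
    def predict(self, image: np.ndarray, score_threshold: float = 0.5,
                nms_iou_test: float = 0.3, rpn_spec: RPNSpec | None = None):
        """Detect objects in an RGB uint8 image; returns list of Detection."""
        if score_threshold >= 1.0:
            return []
        self.eval()
        orig_h, orig_w = image.shape[:2]
        boxed, (scale, pad_x, pad_y) = letterbox_image(image, self.input_size)
        with nn.no_grad():
            feats = self.extract(self.normalize_image(boxed))
            obj, reg = self.rpn_forward(feats)
            anchors = self.anchors_for(feats)
            spec = rpn_spec or self.rpn_spec
            proposals, _ = propose(obj.numpy(), reg.numpy(), anchors, spec,
                                   self.input_size)
            if len(proposals) == 0:
                return []
            cls_logits, box_deltas = self.roi_forward(feats, proposals)
            logits = cls_logits.numpy()
            logits = logits - logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            refined = clip_boxes(decode_boxes(proposals, box_deltas.numpy()),
                                 self.input_size, self.input_size)
        detections = []
        for ci, name in enumerate(self.class_names, start=1):
            scores = probs[:, ci]
            mask = scores >= score_threshold
            if not mask.any():
                continue
            cls_boxes, cls_scores = refined[mask], scores[mask]
            keep = nms(cls_boxes, cls_scores, nms_iou_test)
            mapped = unletterbox_boxes(cls_boxes[keep], scale, pad_x, pad_y,
                                       orig_w, orig_h)
            for box, s in zip(mapped, cls_scores[keep]):
                if box[2] - box[0] >= 1 and box[3] - box[1] >= 1:
                    detections.append(Detection(tuple(box), name, float(s)))
        detections.sort(key=lambda d: -d.score)
        return detections

    # ---------------------------------------------------------- checkpoints
    def save(self, path):
        import pickle

        state = {"class_names": self.class_names,
                 "state_dict": self.state_dict()}
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    def load(self, path):
        import pickle

        with open(path, "rb") as fh:
            state = pickle.load(fh)
        self.load_state_dict(state["state_dict"])
        return self
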