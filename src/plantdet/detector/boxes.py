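"""Box utilities: IoU, greedy NMS, delta coding and letterbox mapping.

All boxes are (x1, y1, x2, y2), 0-based half-open, in pixels.
"""
from __future__ import annotations

import numpy as np

from ..eval_metrics import iou_matrix

__all__ = ["nms", "encode_boxes", "decode_boxes", "clip_boxes",
           "letterbox_params", "letterbox_image", "unletterbox_boxes",
           "iou_matrix"]


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64)
    order = np.argsort(-scores, kind="stable")
    keep = []
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    while order.size:
        i = order[0]
        keep.append(i)
        rest = order[1:]
        ix1 = np.maximum(boxes[i, 0], boxes[rest, 0])
        iy1 = np.maximum(boxes[i, 1], boxes[rest, 1])
        ix2 = np.minimum(boxes[i, 2], boxes[rest, 2])
        iy2 = np.minimum(boxes[i, 3], boxes[rest, 3])
        inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
        union = areas[i] + areas[rest] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            iou = np.where(union > 0, inter / union, 0.0)
        order = rest[iou <= iou_thr]
    return np.array(keep, dtype=np.int64)


def encode_boxes(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Center/size parameterization of gt relative to anchors."""
    anchors = np.asarray(anchors, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gx = gt[:, 0] + 0.5 * gw
    gy = gt[:, 1] + 0.5 * gh
    return np.stack([(gx - ax) / aw, (gy - ay) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1)


def decode_boxes(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    anchors = np.asarray(anchors, dtype=np.float64)
    deltas = np.asarray(deltas, dtype=np.float64)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    cx = ax + deltas[:, 0] * aw
    cy = ay + deltas[:, 1] * ah
    w = aw * np.exp(np.clip(deltas[:, 2], -10, 10))
    h = ah * np.exp(np.clip(deltas[:, 3], -10, 10))
    return np.stack([cx - 0.5 * w, cy - 0.5 * h, cx + 0.5 * w, cy + 0.5 * h],
                    axis=1)


def clip_boxes(boxes: np.ndarray, width: int, height: int) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64).copy()
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, width)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, height)
    return boxes


def letterbox_params(width: int, height: int, size: int):
    """Scale and (left, top) padding for an aspect-preserving square resize."""
    scale = size / max(width, height)
    nw, nh = int(round(width * scale)), int(round(height * scale))
    pad_x = (size - nw) // 2
    pad_y = (size - nh) // 2
    return scale, pad_x, pad_y, nw, nh


def letterbox_image(img: np.ndarray, size: int, fill: int = 128):
    """Aspect-preserving resize onto a gray size x size canvas."""
    from PIL import Image

    h, w = img.shape[:2]
    scale, pad_x, pad_y, nw, nh = letterbox_params(w, h, size)
    resized = Image.fromarray(img).resize((nw, nh), Image.BILINEAR)
    canvas = Image.new("RGB", (size, size), (fill, fill, fill))
    canvas.paste(resized, (pad_x, pad_y))
    return np.asarray(canvas), (scale, pad_x, pad_y)


def letterbox_boxes(boxes: np.ndarray, scale: float, pad_x: int, pad_y: int):
    boxes = np.asarray(boxes, dtype=np.float64) * scale
    boxes[:, 0::2] += pad_x
    boxes[:, 1::2] += pad_y
    return boxes


def unletterbox_boxes(boxes: np.ndarray, scale: float, pad_x: int, pad_y: int,
                      width: int, height: int):
    boxes = np.asarray(boxes, dtype=np.float64).copy()
    boxes[:, 0::2] -= pad_x
    boxes[:, 1::2] -= pad_y
    boxes /= scale
    return clip_boxes(boxes, width, height)
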