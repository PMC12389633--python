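"""Detection evaluation: greedy IoU matching, P/R/F1, AP and means.

Matching is the standard VOC protocol: detections are visited in
descending score order and greedily claim the highest-IoU unmatched
ground truth of their class within the same image; duplicate hits count
as false positives.  AP is the area under the monotone (all-point
interpolated) precision-recall envelope, with an optional 11-point mode.
Reported percentages are rounded half-up, matching tabular conventions.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "MatchResult", "ClassMetrics", "Summary", "box_iou", "iou_matrix",
    "match_detections", "precision_recall_f1", "average_precision",
    "summarize", "ablation_deltas", "evaluate", "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def box_iou(a, b) -> float:
    """IoU of two boxes in (x1, y1, x2, y2) half-open coordinates."""
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix2 - ix1), max(0.0, iy2 - iy1)
    inter = iw * ih
    if inter <= 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU, a: (N,4), b: (M,4)."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int

    def __add__(self, other):
        return MatchResult(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn)


@dataclass
class ClassMetrics:
    class_name: str
    precision: float
    recall: float
    f1: float
    ap: float = 0.0
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class Summary:
    m_ap: float
    m_precision: float
    m_recall: float
    m_f1: float
    n_classes: int


def _match_flags(dets, gts, iou_thr):
    """Greedy per-image matching; returns tp flags aligned to score-sorted dets.

    dets: sequence of (image_id, score, box); gts: sequence of (image_id, box),
    both restricted to a single class.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    gt_by_img: dict = {}
    for img, box in gts:
        gt_by_img.setdefault(img, []).append(np.asarray(box, dtype=np.float64))
    used = {img: np.zeros(len(v), dtype=bool) for img, v in gt_by_img.items()}
    tp_flags = np.zeros(len(dets), dtype=bool)
    for rank, i in enumerate(order):
        img, _score, box = dets[i]
        cands = gt_by_img.get(img)
        if not cands:
            continue
        ious = np.array([box_iou(box, g) for g in cands])
        # highest-IoU *unmatched* ground truth; hits on already-matched
        # ground truths fall through and count as false positives
        avail = ~used[img]
        if avail.any():
            masked = np.where(avail, ious, -1.0)
            best = int(np.argmax(masked))
            if masked[best] >= iou_thr:
                used[img][best] = True
                tp_flags[rank] = True
    scores = np.array([dets[i][1] for i in order])
    return tp_flags, scores, len(gts)


def match_detections(dets, gts, iou_thr: float = 0.5) -> MatchResult:
    """Count TP/FP/FN for one class; dets must carry descending-sortable scores."""
    tp_flags, _scores, n_gt = _match_flags(dets, gts, iou_thr)
    tp = int(tp_flags.sum())
    return MatchResult(tp=tp, fp=len(dets) - tp, fn=n_gt - tp)


def precision_recall_f1(m: MatchResult, class_name: str = "") -> ClassMetrics:
    p = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else 0.0
    r = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return ClassMetrics(class_name, p, r, f1, tp=m.tp, fp=m.fp, fn=m.fn)


def average_precision(dets, gts, iou_thr: float = 0.5,
                      eleven_point: bool = False) -> float:
    """AP for one class from scored detections and ground truths."""
    if not gts:
        return 0.0
    if not dets:
        return 0.0
    tp_flags, _scores, n_gt = _match_flags(dets, gts, iou_thr)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    if eleven_point:
        ap = 0.0
        for t in np.linspace(0, 1, 11):
            mask = recall >= t
            ap += (precision[mask].max() if mask.any() else 0.0) / 11.0
        return float(ap)
    # monotone envelope then step integration over recall
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def summarize(per_class: list[ClassMetrics]) -> Summary:
    if not per_class:
        raise ValueError("summarize requires at least one class")
    return Summary(
        m_ap=float(np.mean([c.ap for c in per_class])),
        m_precision=float(np.mean([c.precision for c in per_class])),
        m_recall=float(np.mean([c.recall for c in per_class])),
        m_f1=float(np.mean([c.f1 for c in per_class])),
        n_classes=len(per_class),
    )


def ablation_deltas(a, b):
    """Per-metric absolute (b - a) and relative (b - a)/a changes.

    Accepts two mappings metric -> value, or two Summary objects.
    Relative change is None when the baseline is zero.
    """
    if isinstance(a, Summary):
        a = {"m_ap": a.m_ap, "m_precision": a.m_precision,
             "m_recall": a.m_recall, "m_f1": a.m_f1}
    if isinstance(b, Summary):
        b = {"m_ap": b.m_ap, "m_precision": b.m_precision,
             "m_recall": b.m_recall, "m_f1": b.m_f1}
    if set(a) != set(b):
        raise ValueError("ablation_deltas requires identical metric sets")
    out = {}
    for k in a:
        diff = b[k] - a[k]
        rel = (diff / a[k]) if a[k] != 0 else None
        out[k] = {"abs": diff, "rel": rel}
    return out


def evaluate(detections, annotations, class_names=None, iou_thr: float = 0.5,
             score_thr: float = 0.5):
    """Full per-class evaluation.

    detections: iterable of (image_id, class_name, score, box);
    annotations: iterable of (image_id, class_name, box).
    P/R/F1 are computed at `score_thr`; AP over all detections.
    Returns (list of ClassMetrics, Summary).
    """
    detections = list(detections)
    annotations = list(annotations)
    if class_names is None:
        class_names = sorted({a[1] for a in annotations})
    per_class = []
    for cls in class_names:
        dets = [(d[0], d[2], d[3]) for d in detections if d[1] == cls]
        gts = [(a[0], a[2]) for a in annotations if a[1] == cls]
        thresholded = [d for d in dets if d[1] >= score_thr]
        cm = precision_recall_f1(match_detections(thresholded, gts, iou_thr), cls)
        cm.ap = average_precision(dets, gts, iou_thr)
        per_class.append(cm)
    return per_class, summarize(per_class)
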