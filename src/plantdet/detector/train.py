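"""Target assignment, multi-task losses and the training loop.

RPN anchors: positive at IoU >= 0.7 with any ground truth (or best match
per ground truth), negative below 0.3, sampled 256 per image at 1:1.
Head RoIs: foreground at IoU >= 0.5, sampled 128 at 1:3; ground-truth
boxes are appended to the proposal set during training.  Losses are
binary cross-entropy (RPN objectness), cross-entropy over classes +
background (head) and smooth-L1 on positive box deltas.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Adam, SGD
from ..nn import functional as F
from .boxes import encode_boxes, iou_matrix, letterbox_boxes, letterbox_image
from .model import FasterRCNN, propose

__all__ = ["TrainSpec", "rpn_targets", "roi_targets", "detection_loss",
           "train_step", "train", "recalibrate_bn"]


@dataclass(frozen=True)
class TrainSpec:
    input_size: int = 600
    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 100
    optimizer: str = "adam"
    momentum: float = 0.9  # first-moment decay (beta1) for adam
    weight_decay: float = 5e-4
    rpn_batch: int = 256
    rpn_pos_fraction: float = 0.5
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    roi_batch: int = 128
    roi_fg_fraction: float = 0.25
    roi_fg_iou: float = 0.5
    max_steps: int | None = None  # overrides epochs when set

    def __post_init__(self):
        if min(self.input_size, self.learning_rate, self.batch_size,
               self.epochs, self.weight_decay) < 0:
            raise ValueError("train spec values must be non-negative")


def rpn_targets(anchors: np.ndarray, gt_boxes: np.ndarray, spec: TrainSpec,
                rng: np.random.Generator):
    """Sampled anchor labels (1/0) and positive box deltas.

    Returns (sample_idx, labels, pos_idx, pos_deltas).
    """
    n = len(anchors)
    labels = np.full(n, -1, dtype=np.int64)  # -1 = ignored
    if len(gt_boxes):
        ious = iou_matrix(anchors, gt_boxes)
        max_iou = ious.max(axis=1)
        argmax_gt = ious.argmax(axis=1)
        labels[max_iou < spec.rpn_neg_iou] = 0
        labels[max_iou >= spec.rpn_pos_iou] = 1
        # guarantee each ground truth at least one positive anchor
        best_per_gt = ious.argmax(axis=0)
        labels[best_per_gt] = 1
    else:
        labels[:] = 0
        argmax_gt = np.zeros(n, dtype=np.int64)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n_pos = min(len(pos), int(spec.rpn_batch * spec.rpn_pos_fraction))
    n_neg = min(len(neg), spec.rpn_batch - n_pos)
    pos = rng.permutation(pos)[:n_pos]
    neg = rng.permutation(neg)[:n_neg]
    sample_idx = np.concatenate([pos, neg])
    sample_labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    if len(pos) and len(gt_boxes):
        deltas = encode_boxes(anchors[pos], gt_boxes[argmax_gt[pos]])
    else:
        deltas = np.zeros((0, 4))
    return sample_idx, sample_labels, pos, deltas


def roi_targets(proposals: np.ndarray, gt_boxes: np.ndarray,
                gt_labels: np.ndarray, spec: TrainSpec,
                rng: np.random.Generator):
    """Sampled RoIs with class labels (0 = background) and fg deltas.

    Returns (rois, labels, fg_mask, fg_deltas).
    """
    rois = np.concatenate([proposals, gt_boxes]) if len(gt_boxes) else proposals
    ious = iou_matrix(rois, gt_boxes) if len(gt_boxes) else np.zeros((len(rois), 1))
    max_iou = ious.max(axis=1)
    argmax_gt = ious.argmax(axis=1)
    fg = np.flatnonzero(max_iou >= spec.roi_fg_iou)
    bg = np.flatnonzero(max_iou < spec.roi_fg_iou)
    n_fg = min(len(fg), int(spec.roi_batch * spec.roi_fg_fraction))
    n_bg = min(len(bg), spec.roi_batch - n_fg)
    fg = rng.permutation(fg)[:n_fg]
    bg = rng.permutation(bg)[:n_bg]
    keep = np.concatenate([fg, bg]).astype(np.int64)
    labels = np.zeros(len(keep), dtype=np.int64)
    if len(gt_boxes):
        labels[:n_fg] = gt_labels[argmax_gt[fg]] + 1  # shift past background
    fg_mask = np.zeros(len(keep), dtype=bool)
    fg_mask[:n_fg] = True
    if n_fg and len(gt_boxes):
        fg_deltas = encode_boxes(rois[fg], gt_boxes[argmax_gt[fg]])
    else:
        fg_deltas = np.zeros((0, 4))
    return rois[keep], labels, fg_mask, fg_deltas


def detection_loss(cls_scores, box_preds, labels, fg_mask, fg_deltas):
    """Head loss: cross-entropy + smooth-L1 on foreground RoIs."""
    cls_loss = F.cross_entropy(cls_scores, labels)
    if fg_mask.any():
        reg_loss = F.smooth_l1(box_preds[np.flatnonzero(fg_mask)], fg_deltas)
    else:
        reg_loss = None
    total = cls_loss if reg_loss is None else cls_loss + reg_loss
    return {"cls": cls_loss, "reg": reg_loss, "total": total}


def train_step(model: FasterRCNN, image: np.ndarray, gt_boxes: np.ndarray,
               gt_labels: np.ndarray, spec: TrainSpec,
               rng: np.random.Generator):
    """Forward + backward for one image; returns the scalar loss value."""
    size = model.input_size
    boxed, (scale, pad_x, pad_y) = letterbox_image(image, size)
    gt = letterbox_boxes(gt_boxes, scale, pad_x, pad_y) if len(gt_boxes) \
        else np.zeros((0, 4))
    feats = model.extract(model.normalize_image(boxed))
    obj, reg = model.rpn_forward(feats)
    anchors = model.anchors_for(feats)

    s_idx, s_labels, pos_idx, pos_deltas = rpn_targets(anchors, gt, spec, rng)
    rpn_cls = F.bce_with_logits(obj[s_idx], s_labels)
    losses = [rpn_cls]
    if len(pos_idx):
        losses.append(F.smooth_l1(reg[pos_idx], pos_deltas))

    proposals, _ = propose(obj.numpy(), reg.numpy(), anchors, model.rpn_spec, size)
    rois, labels, fg_mask, fg_deltas = roi_targets(proposals, gt, gt_labels,
                                                   spec, rng)
    cls_scores, box_preds = model.roi_forward(feats, rois)
    head = detection_loss(cls_scores, box_preds, labels, fg_mask, fg_deltas)
    losses.append(head["total"])
    total = losses[0]
    for extra in losses[1:]:
        total = total + extra
    total.backward()
    return float(total.data)


def make_optimizer(model: FasterRCNN, spec: TrainSpec):
    params = model.parameters()
    if spec.optimizer.lower() == "adam":
        return Adam(params, lr=spec.learning_rate,
                    betas=(spec.momentum, 0.999),
                    weight_decay=spec.weight_decay)
    return SGD(params, lr=spec.learning_rate, momentum=spec.momentum,
               weight_decay=spec.weight_decay)


def recalibrate_bn(model: FasterRCNN, images, max_images: int = 20):
    """Re-estimate BatchNorm running statistics after training.

    Short schedules leave running averages biased by early-training
    activation scales; this replaces them with the plain average of
    batch statistics over (up to max_images) training images.
    """
    from ..nn import BatchNorm2d, no_grad

    bns = [m for _, m in model.named_modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    model.train()
    size = model.input_size
    with no_grad():
        for k, img in enumerate(list(images)[:max_images]):
            for bn in bns:
                bn.momentum = 1.0 / (k + 1)  # cumulative moving average
            boxed, _ = letterbox_image(img, size)
            feats = model.extract(model.normalize_image(boxed))
            obj, reg = model.rpn_forward(feats)
            anchors = model.anchors_for(feats)
            proposals, _ = propose(obj.numpy(), reg.numpy(), anchors,
                                   model.rpn_spec, size)
            if len(proposals):
                model.roi_forward(feats, proposals)
    for bn, m in zip(bns, saved):
        bn.momentum = m
    model.eval()


def train(model: FasterRCNN, dataset, spec: TrainSpec = TrainSpec(),
          seed: int = 0, log_every: int = 0):
    """Train on a list of (image, gt_boxes, gt_labels) samples.

    gt_labels are integer class indices into model.class_names.
    Returns the per-step loss trace; deterministic under the seed.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training requires a non-empty dataset")
    rng = np.random.default_rng(seed)
    opt = make_optimizer(model, spec)
    model.train()
    steps_per_epoch = max(1, len(dataset) // spec.batch_size)
    total_steps = spec.max_steps if spec.max_steps is not None \
        else spec.epochs * steps_per_epoch
    trace = []
    order = rng.permutation(len(dataset))
    cursor = 0
    for step in range(total_steps):
        opt.zero_grad()
        batch_loss = 0.0
        for _ in range(spec.batch_size):
            if cursor >= len(order):
                order = rng.permutation(len(dataset))
                cursor = 0
            img, boxes, labels = dataset[order[cursor]]
            cursor += 1
            batch_loss += train_step(model, img, np.asarray(boxes, dtype=np.float64),
                                     np.asarray(labels, dtype=np.int64), spec, rng)
        # average accumulated gradients over the batch
        if spec.batch_size > 1:
            for p in model.parameters():
                if p.grad is not None:
                    p.grad /= spec.batch_size
        opt.step()
        trace.append(batch_loss / spec.batch_size)
        if log_every and (step + 1) % log_every == 0:
            print(f"step {step + 1}/{total_steps} loss {trace[-1]:.4f}")
    recalibrate_bn(model, (img for img, _b, _l in dataset))
    return trace
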