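"""Axis-aligned box utilities shared across detection, ensembling and evaluation.

Boxes are pixel rectangles ``(x1, y1, x2, y2)``, 0-based, half-open
``[x1, x2) x [y1, y2)``, so ``width = x2 - x1``.  The 1-based inclusive
Pascal VOC convention exists only at XML boundaries (see
:mod:`weedspot.rgbd_io`).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "box_area",
    "iou_matrix",
    "clip_boxes",
    "encode_box_deltas",
    "decode_box_deltas",
    "smooth_l1",
    "nms",
]


def box_area(boxes: np.ndarray) -> np.ndarray:
    """Areas of an ``(N, 4)`` array of boxes (0 for degenerate boxes)."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    w = np.maximum(boxes[:, 2] - boxes[:, 0], 0.0)
    h = np.maximum(boxes[:, 3] - boxes[:, 1], 0.0)
    return w * h


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union between ``(N, 4)`` and ``(M, 4)`` boxes."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.maximum(x2 - x1, 0.0) * np.maximum(y2 - y1, 0.0)
    union = box_area(a)[:, None] + box_area(b)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def clip_boxes(boxes: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    """Clip boxes to ``[0, W] x [0, H]``; ``image_size`` is ``(H, W)``."""
    h, w = image_size
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float)).copy()
    boxes[:, [0, 2]] = np.clip(boxes[:, [0, 2]], 0, w)
    boxes[:, [1, 3]] = np.clip(boxes[:, [1, 3]], 0, h)
    return boxes


def _to_cxcywh(boxes: np.ndarray) -> tuple[np.ndarray, ...]:
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    w = boxes[:, 2] - boxes[:, 0]
    h = boxes[:, 3] - boxes[:, 1]
    cx = boxes[:, 0] + 0.5 * w
    cy = boxes[:, 1] + 0.5 * h
    return cx, cy, w, h


def encode_box_deltas(gt_boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Encode ground-truth boxes as dimensionless deviations from anchors.

    Standard Faster R-CNN parameterisation: ``t_x = (x* - x_a) / w_a``,
    ``t_y = (y* - y_a) / h_a``, ``t_w = log(w* / w_a)``, ``t_h = log(h* / h_a)``
    where ``(x, y)`` are box centres.  ``decode_box_deltas`` is its exact
    inverse.
    """
    x, y, w, h = _to_cxcywh(gt_boxes)
    xa, ya, wa, ha = _to_cxcywh(anchors)
    if np.any(wa <= 0) or np.any(ha <= 0):
        raise ValueError("anchors must have positive width and height")
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("ground-truth boxes must have positive extent")
    return np.stack(
        [(x - xa) / wa, (y - ya) / ha, np.log(w / wa), np.log(h / ha)], axis=1
    )


def decode_box_deltas(deltas: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Apply predicted deviations to anchors, returning ``(x1, y1, x2, y2)`` boxes."""
    deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
    xa, ya, wa, ha = _to_cxcywh(anchors)
    if np.any(wa <= 0) or np.any(ha <= 0):
        raise ValueError("anchors must have positive width and height")
    cx = deltas[:, 0] * wa + xa
    cy = deltas[:, 1] * ha + ya
    w = np.exp(deltas[:, 2]) * wa
    h = np.exp(deltas[:, 3]) * ha
    return np.stack([cx - 0.5 * w, cy - 0.5 * h, cx + 0.5 * w, cy + 0.5 * h], axis=1)


def smooth_l1(x: np.ndarray) -> np.ndarray:
    """Smooth L1: ``0.5 x^2`` if ``|x| < 1`` else ``|x| - 0.5``.

    Continuous and C^1 at ``|x| = 1``; the quadratic zone makes the box
    regression loss robust to outliers while keeping gradients bounded.
    """
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    return np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression.

    Processes boxes in descending score order, suppressing any box whose IoU
    with an already-kept box exceeds ``iou_threshold``.  Returns the indices
    of kept boxes (in descending-score order).  Ties in score are broken by
    original index, so the result is deterministic.
    """
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    scores = np.asarray(scores, dtype=float)
    if boxes.shape[0] == 0:
        return np.empty(0, dtype=int)
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    iou = iou_matrix(boxes, boxes)
    suppressed = np.zeros(boxes.shape[0], dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        suppressed |= iou[i] > iou_threshold
    return np.asarray(keep, dtype=int)
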