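"""Anchor generation and training-label assignment for the region proposal networks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import encode_box_deltas, iou_matrix

__all__ = ["AnchorConfig", "generate_anchors", "assign_anchor_labels", "RPNTrainingBatch"]

# label codes
POSITIVE, NEGATIVE, IGNORE = 1, 0, -1


@dataclass
class AnchorConfig:
    """Anchor scales (box side in pixels) and aspect ratios per grid cell.

    Three scales x three ratios is the classic region-proposal default; the
    optional 0.33 ratio suits thin elongated grass-weed boxes and can be
    appended via ``ratios``.
    """

    scales: tuple[float, ...] = (32.0, 64.0, 128.0)
    ratios: tuple[float, ...] = (0.5, 1.0, 2.0)

    @property
    def per_cell(self) -> int:
        return len(self.scales) * len(self.ratios)


def generate_anchors(feature_size: tuple[int, int], stride: int, config: AnchorConfig) -> np.ndarray:
    """Tile anchors over a feature grid; returns ``(H*W*A, 4)`` boxes.

    Anchor centres sit at ``(j + 0.5) * stride, (i + 0.5) * stride`` in image
    pixels; ``ratio`` is height/width at constant area.
    """
    fh, fw = feature_size
    boxes = []
    base = []
    for scale in config.scales:
        for ratio in config.ratios:
            w = scale / np.sqrt(ratio)
            h = scale * np.sqrt(ratio)
            base.append((w, h))
    base = np.array(base)  # (A, 2)
    ys, xs = np.mgrid[0:fh, 0:fw]
    cx = (xs + 0.5).ravel() * stride
    cy = (ys + 0.5).ravel() * stride
    for w, h in base:
        boxes.append(np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1))
    # order: cell-major, anchor-minor — reshape (A, HW, 4) -> (HW, A, 4)
    arr = np.stack(boxes, axis=0).transpose(1, 0, 2).reshape(-1, 4)
    return arr


@dataclass
class RPNTrainingBatch:
    """Per-anchor supervision for one image.

    ``labels`` uses 1 / 0 / -1 for positive / negative / ignore; positives
    carry their matched ground-truth box and encoded target deltas.  The
    classification term is normalised by the sampled mini-batch size
    ``n_cls`` and the regression term by the number of anchor locations
    ``n_reg``; ``lam`` balances the two.
    """

    labels: np.ndarray
    target_deltas: np.ndarray
    matched_gt: np.ndarray
    n_cls: int
    n_reg: int
    lam: float = 10.0
    sample_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def assign_anchor_labels(
    anchors: np.ndarray,
    gt_boxes: np.ndarray,
    pos_iou: float = 0.7,
    neg_iou: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Label anchors against ground-truth boxes.

    Two kinds of anchor are positive: (i) for each ground-truth box, the
    anchor(s) with the highest IoU overlap with it — so every ground-truth
    box is guaranteed at least one positive anchor even when nothing clears
    the threshold — and (ii) any anchor with IoU > ``pos_iou`` with some
    ground-truth box.  Anchors whose best IoU falls below ``neg_iou`` are
    negative; the rest are ignored.  Returns ``(labels, matched_gt_index)``.
    """
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    n = anchors.shape[0]
    labels = np.full(n, IGNORE, dtype=int)
    matched = np.zeros(n, dtype=int)
    if gt_boxes.shape[0] == 0:
        labels[:] = NEGATIVE
        return labels, matched
    iou = iou_matrix(anchors, gt_boxes)  # (n, g)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(n), best_gt]
    matched = best_gt
    labels[best_iou < neg_iou] = NEGATIVE
    labels[best_iou > pos_iou] = POSITIVE
    # rule (i): each gt claims its best-overlapping anchor regardless of the
    # threshold; when two gts prefer the same anchor, the runner-up anchor is
    # claimed instead so every overlapping gt keeps at least one positive
    gt_best = iou.max(axis=0)
    claimed: set[int] = set()
    for g in np.argsort(-gt_best):
        if gt_best[g] <= 0:
            continue  # gt overlaps no anchor at all (degenerate)
        order = np.argsort(-iou[:, g], kind="stable")
        for a in order:
            if iou[a, g] <= 0:
                break
            if a not in claimed:
                claimed.add(int(a))
                labels[a] = POSITIVE
                matched[a] = g
                break
        # anchors tied with the winner at the same IoU are also positive
        winners = np.nonzero(iou[:, g] == gt_best[g])[0]
        for a in winners:
            if labels[a] != POSITIVE:
                labels[a] = POSITIVE
                matched[a] = g
    return labels, matched


def build_rpn_batch(
    anchors: np.ndarray,
    gt_boxes: np.ndarray,
    rng: np.random.Generator,
    batch_size: int = 256,
    pos_fraction: float = 0.5,
    lam: float = 10.0,
    pos_iou: float = 0.7,
    neg_iou: float = 0.3,
) -> RPNTrainingBatch:
    """Sample a balanced anchor mini-batch (up to 1:1 positive:negative)."""
    labels, matched = assign_anchor_labels(anchors, gt_boxes, pos_iou, neg_iou)
    pos_idx = np.nonzero(labels == POSITIVE)[0]
    neg_idx = np.nonzero(labels == NEGATIVE)[0]
    n_pos_target = int(batch_size * pos_fraction)
    if len(pos_idx) > n_pos_target:
        pos_sample = rng.choice(pos_idx, size=n_pos_target, replace=False)
    elif len(pos_idx) > 0:
        # few positives: repeat each up to 4x (capped at the target) so the
        # objectness signal is not drowned by the negative majority
        reps = min(4, max(1, n_pos_target // len(pos_idx)))
        pos_sample = np.tile(pos_idx, reps)
    else:
        pos_sample = pos_idx
    n_neg = min(len(neg_idx), batch_size - len(pos_sample))
    if len(neg_idx) > n_neg:
        neg_idx = rng.choice(neg_idx, size=n_neg, replace=False)
    sample_idx = np.concatenate([pos_sample, neg_idx]).astype(int)

    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    target_deltas = np.zeros((anchors.shape[0], 4))
    if gt_boxes.shape[0] and len(pos_idx):
        target_deltas[pos_idx] = encode_box_deltas(gt_boxes[matched[pos_idx]], anchors[pos_idx])

    full_labels = np.full(anchors.shape[0], IGNORE, dtype=int)
    full_labels[pos_idx] = POSITIVE
    full_labels[neg_idx] = NEGATIVE
    return RPNTrainingBatch(
        labels=full_labels,
        target_deltas=target_deltas,
        matched_gt=matched,
        n_cls=max(len(sample_idx), 1),
        n_reg=anchors.shape[0] // max(1, _anchors_per_cell(anchors)),
        lam=lam,
        sample_idx=sample_idx,
    )


def _anchors_per_cell(anchors: np.ndarray) -> int:
    """Infer anchors-per-location from repeated centres (cell-major layout)."""
    if anchors.shape[0] == 0:
        return 1
    cx = (anchors[:, 0] + anchors[:, 2]) / 2
    cy = (anchors[:, 1] + anchors[:, 3]) / 2
    first = (cx == cx[0]) & (cy == cy[0])
    run = 0
    for flag in first:
        if not flag:
            break
        run += 1
    return max(run, 1)
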