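"""Detection metrics: per-class AP, mAP, and intersection-over-ground-truth.

AP is the area under the precision-recall curve, computed with all-point
interpolation by default (the monotone right-envelope of the raw curve;
an 11-point variant is available).  mAP is the unweighted mean over the
two weed classes.

IoG — intersection over ground truth — measures what fraction of the total
labelled weed *area* the detections cover: the pixel area of the
intersection between the union of above-threshold detection boxes and the
union of ground-truth boxes, divided by the ground-truth union area.
Unlike AP it does not punish a detector for splitting one weed cluster
into several boxes where the annotator drew one (or vice versa), which
makes it robust to the granularity of labelling in dense vegetation.
IoG is class-agnostic by default; a per-class variant is exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boxes import iou_matrix
from .detections import DetectionSet
from .rgbd_io import AnnotationSet, CLASS_NAMES

__all__ = ["EvalReport", "match_detections", "average_precision", "iog", "evaluate"]


@dataclass
class EvalReport:
    """Per-class AP (%), mAP (%), IoG (%), and PR curves."""

    per_class_ap: dict[str, float]
    map: float
    iog: float
    pr_curves: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (recall, precision)
    iou_threshold: float
    iog_score_threshold: float

    def __post_init__(self) -> None:
        for v in [self.map, self.iog, *self.per_class_ap.values()]:
            if np.isfinite(v) and not (0.0 <= v <= 100.0 + 1e-9):
                raise ValueError("AP/mAP/IoG must lie in [0, 100]")


def match_detections(
    dets: DetectionSet, gts: AnnotationSet, iou_threshold: float = 0.5
) -> np.ndarray:
    """Flag each detection as TP (True) or FP (False).

    Detections are processed in descending score order; a detection is a
    true positive iff its IoU with some not-yet-matched same-class
    ground-truth box reaches the threshold (the best-overlapping one is
    consumed, so each ground truth matches at most once).
    """
    dets = dets.sort()
    tp = np.zeros(len(dets), dtype=bool)
    gt_boxes = gts.boxes()
    gt_labels = gts.labels()
    matched = np.zeros(len(gt_labels), dtype=bool)
    if len(gt_labels) == 0 or len(dets) == 0:
        return tp
    iou = iou_matrix(dets.boxes, gt_boxes)
    for i in range(len(dets)):
        candidates = [
            j
            for j in range(len(gt_labels))
            if not matched[j] and gt_labels[j] == dets.labels[i] and iou[i, j] >= iou_threshold
        ]
        if candidates:
            j = max(candidates, key=lambda j: iou[i, j])
            matched[j] = True
            tp[i] = True
    return tp


def average_precision(
    tp_flags: np.ndarray, n_gt: int, interpolation: str = "all_point"
) -> tuple[float, np.ndarray, np.ndarray]:
    """AP (%) from score-ordered TP/FP flags and the ground-truth count.

    Returns ``(ap_percent, recall, precision)``; the PR arrays are the raw
    cumulative curve.  ``n_gt == 0`` yields NaN (undefined AP).
    """
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if n_gt == 0:
        return float("nan"), np.zeros(0), np.zeros(0)
    if tp_flags.size == 0:
        return 0.0, np.zeros(0), np.zeros(0)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    if interpolation == "all_point":
        r = np.concatenate([[0.0], recall, [recall[-1]]])
        p = np.concatenate([[0.0], precision, [0.0]])
        # monotone right-envelope of precision
        for i in range(len(p) - 2, -1, -1):
            p[i] = max(p[i], p[i + 1])
        ap = float(np.sum((r[1:] - r[:-1]) * p[1:]))
    elif interpolation == "11_point":
        ap = 0.0
        for r_level in np.linspace(0, 1, 11):
            mask = recall >= r_level - 1e-12
            ap += (precision[mask].max() if mask.any() else 0.0) / 11.0
    else:
        raise ValueError("interpolation must be 'all_point' or '11_point'")
    return 100.0 * ap, recall, precision


def _rasterize_union(boxes: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    h, w = size
    mask = np.zeros((h, w), dtype=bool)
    for x1, y1, x2, y2 in np.atleast_2d(boxes):
        xa = int(np.clip(np.round(x1), 0, w))
        xb = int(np.clip(np.round(x2), 0, w))
        ya = int(np.clip(np.round(y1), 0, h))
        yb = int(np.clip(np.round(y2), 0, h))
        mask[ya:yb, xa:xb] = True
    return mask


def iog(
    dets: dict[str, DetectionSet],
    anns: dict[str, AnnotationSet],
    score_threshold: float = 0.3,
    class_name: str | None = None,
) -> float:
    """Intersection over ground truth (%), aggregated over the dataset.

    Per image, the union of above-threshold detection boxes and the union
    of ground-truth boxes are rasterised at pixel resolution; intersection
    and ground-truth areas are summed over all images before dividing.
    Class-agnostic unless ``class_name`` is given.
    """
    inter_area = 0
    gt_area = 0
    for image_id, ann in anns.items():
        if class_name is not None:
            ann = AnnotationSet(
                ann.image_size, [o for o in ann.objects if o.class_name == class_name]
            )
        gt_mask = _rasterize_union(ann.boxes(), ann.image_size) if len(ann.objects) else None
        ds = dets.get(image_id, DetectionSet()).filter_scores(score_threshold)
        if class_name is not None:
            ds = ds.for_class(class_name)
        if gt_mask is not None:
            det_mask = _rasterize_union(ds.boxes, ann.image_size) if len(ds) else np.zeros_like(gt_mask)
            inter_area += int((gt_mask & det_mask).sum())
            gt_area += int(gt_mask.sum())
    if gt_area == 0:
        raise ValueError("IoG undefined: total ground-truth area is zero")
    return 100.0 * inter_area / gt_area


def evaluate(
    dets: dict[str, DetectionSet],
    anns: dict[str, AnnotationSet],
    iou_threshold: float = 0.5,
    iog_score_threshold: float = 0.3,
    interpolation: str = "all_point",
) -> EvalReport:
    """Full evaluation over a dataset of per-image detections and annotations.

    ``dets`` and ``anns`` map image ids to detection / annotation sets;
    every annotated image must be present in ``dets`` (an empty
    DetectionSet is fine).  A class with no ground-truth instances has
    undefined AP and is excluded from mAP with a warning.
    """
    missing = sorted(set(anns) - set(dets))
    if missing:
        raise ValueError(f"no detections supplied for annotated image ids: {missing}")

    per_class_ap: dict[str, float] = {}
    pr_curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cname in CLASS_NAMES:
        scores_all: list[float] = []
        tp_all: list[bool] = []
        n_gt = 0
        for image_id, ann in anns.items():
            ds = dets[image_id].for_class(cname).sort()
            sub_ann = AnnotationSet(
                ann.image_size, [o for o in ann.objects if o.class_name == cname]
            )
            n_gt += len(sub_ann.objects)
            tp = match_detections(ds, sub_ann, iou_threshold)
            scores_all.extend(ds.scores.tolist())
            tp_all.extend(tp.tolist())
        order = np.argsort(-np.asarray(scores_all), kind="stable") if scores_all else []
        flags = np.asarray(tp_all, dtype=bool)[order] if len(tp_all) else np.zeros(0, dtype=bool)
        ap, recall, precision = average_precision(flags, n_gt, interpolation)
        if np.isnan(ap):
            warnings.warn(f"AP undefined for class {cname!r} (no ground truth); excluded from mAP")
        per_class_ap[cname] = ap
        pr_curves[cname] = (recall, precision)

    defined = [v for v in per_class_ap.values() if not np.isnan(v)]
    map_value = float(np.mean(defined)) if defined else float("nan")
    iog_value = iog(dets, anns, iog_score_threshold)
    return EvalReport(
        per_class_ap=per_class_ap,
        map=map_value,
        iog=iog_value,
        pr_curves=pr_curves,
        iou_threshold=iou_threshold,
        iog_score_threshold=iog_score_threshold,
    )
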