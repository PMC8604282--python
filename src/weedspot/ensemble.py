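"""Decision-level weighted fusion of the three branches' detections.

The ensemble score of a detection ``x`` is the convex-ish combination
``G(x) = alpha * g_rgb(x) + beta * g_pha(x) + (1 - alpha - beta) * g_corr(x)``
with ``alpha, beta >= 0`` and ``alpha + beta <= 1``.  The branch outputs are
box lists, so the combination is realised by clustering same-class boxes
across branches by IoU: each cluster contributes one fused detection whose
score is the weighted sum of its members' scores (absent branches contribute
0) and whose box is the mean of member boxes weighted by
``branch_weight * score`` — so at the corners of the weight simplex the
ensemble reduces *exactly* to a single branch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .boxes import iou_matrix
from .detections import DetectionSet

__all__ = ["EnsembleWeights", "fuse_detections", "grid_search_weights"]


@dataclass
class EnsembleWeights:
    """Ensemble weights for the RGB and PHA (depth) branches.

    The correlated branch receives the remainder ``1 - alpha - beta``.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta > 1 + 1e-9:
            raise ValueError(
                f"weights must satisfy alpha >= 0, beta >= 0, alpha + beta <= 1; "
                f"got alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def gamma(self) -> float:
        return 1.0 - self.alpha - self.beta

    def of(self, branch: str) -> float:
        return {"rgb": self.alpha, "pha": self.beta, "corr": self.gamma}[branch]


def fuse_detections(
    rgb: DetectionSet,
    pha: DetectionSet,
    corr: DetectionSet,
    weights: EnsembleWeights,
    cluster_iou: float = 0.5,
    average_boxes: bool = True,
) -> DetectionSet:
    """Fuse the three branches' detections for one image.

    Same-class detections are clustered greedily in descending raw-score
    order; a detection joins the best-overlapping existing cluster with
    IoU >= ``cluster_iou`` that does not yet hold a member from its branch,
    otherwise it founds a new cluster.  Fused score and box are as in the
    module docstring; clusters whose fused score is 0 (all members from
    zero-weight branches) are dropped.  With ``average_boxes=False`` the
    fused box is the box of the member with the largest weighted score.
    """
    if not isinstance(weights, EnsembleWeights):
        weights = EnsembleWeights(*weights)
    entries = []
    for ds, branch in ((rgb, "rgb"), (pha, "pha"), (corr, "corr")):
        for box, score, label in zip(ds.boxes, ds.scores, ds.labels):
            entries.append((float(score), label, branch, np.asarray(box, dtype=float)))
    entries.sort(key=lambda e: -e[0])

    clusters: list[dict] = []
    for score, label, branch, box in entries:
        best, best_iou = None, cluster_iou
        for cl in clusters:
            if cl["label"] != label or branch in cl["members"]:
                continue
            iou = float(iou_matrix(box[None], cl["box"][None])[0, 0])
            if iou >= best_iou:
                best, best_iou = cl, iou
        if best is None:
            clusters.append({"label": label, "box": box, "members": {branch: (box, score)}})
        else:
            best["members"][branch] = (box, score)

    fused_boxes, fused_scores, fused_labels = [], [], []
    for cl in clusters:
        contributors = [
            (weights.of(branch) * score, box)
            for branch, (box, score) in cl["members"].items()
            if weights.of(branch) * score > 0.0
        ]
        if not contributors:
            continue
        if average_boxes and len(contributors) > 1:
            wsum = sum(w for w, _ in contributors)
            box_out = sum(w * box for w, box in contributors) / wsum
        else:
            box_out = max(contributors, key=lambda c: c[0])[1]
        fused_boxes.append(box_out)
        fused_scores.append(
            sum(weights.of(b) * s for b, (_, s) in cl["members"].items())
        )
        fused_labels.append(cl["label"])
    if not fused_boxes:
        return DetectionSet(source="ensemble")
    return DetectionSet(
        np.array(fused_boxes), np.array(fused_scores), fused_labels, source="ensemble"
    ).sort()


def grid_search_weights(
    branch_outputs: dict[str, dict[str, DetectionSet]],
    annotations: dict[str, "AnnotationSet"],  # noqa: F821 - forward ref
    step: float = 0.05,
    metric: str = "map",
    cluster_iou: float = 0.5,
    match_iou: float = 0.5,
    iog_score_threshold: float = 0.3,
):
    """Exhaustive search over the feasible (alpha, beta) grid.

    ``branch_outputs`` maps image id -> {"rgb"/"pha"/"corr": DetectionSet}.
    Every grid point with ``alpha + beta <= 1`` is scored on the validation
    set by mAP (or IoG with ``metric="iog"``); returns the argmax weights
    and the full score surface as a list of ``(alpha, beta, score)``.
    Ties are broken toward smaller alpha, then smaller beta, so the result
    is independent of image ordering.
    """
    from .evaluation import evaluate

    if not branch_outputs:
        raise ValueError("empty validation set")
    if metric not in ("map", "iog"):
        raise ValueError("metric must be 'map' or 'iog'")
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")

    surface = []
    best = None
    for a, b in itertools.product(range(n + 1), range(n + 1)):
        if a + b > n:
            continue
        w = EnsembleWeights(a * step, b * step)
        fused = {
            img: fuse_detections(d["rgb"], d["pha"], d["corr"], w, cluster_iou)
            for img, d in branch_outputs.items()
        }
        report = evaluate(
            fused, annotations, iou_threshold=match_iou, iog_score_threshold=iog_score_threshold
        )
        score = report.map if metric == "map" else report.iog
        surface.append((w.alpha, w.beta, score))
        if best is None or score > best[0] + 1e-12:
            best = (score, w)
    return best[1], surface
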