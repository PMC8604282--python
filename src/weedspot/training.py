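"""End-to-end SGD training of the three-branch detector.

Each iteration draws one image; the three RPNs (RGB-specific, PHA-specific
and correlated) are trained simultaneously with the same box supervision,
and each branch's RoI head is trained on proposals sampled from its own
RPN plus the ground-truth boxes.  The total loss is the sum of the three
branches' RPN multi-task losses and head losses; optimisation is plain SGD
with momentum and L2 weight decay.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .boxes import clip_boxes, decode_box_deltas, encode_box_deltas, iou_matrix, nms as _nms
from .network import NetworkConfig, WeedDetectionNet, rpn_loss
from .nn import Tensor
from .rgbd_io import AnnotationSet, CLASS_NAMES

__all__ = ["TrainConfig", "TrainResult", "train", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Optimiser hyperparameters.

    Defaults follow the reference training schedule for the full-scale
    network (initial learning rate 0.001, momentum 0.9, weight decay
    0.0001, 1000 iterations per epoch over 300 epochs); small-scale runs
    override ``iterations``.
    """

    initial_learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0001
    iterations_per_epoch: int = 1000
    epochs: int = 300
    iterations: int | None = None  # explicit override of epochs * iters/epoch
    roi_batch_size: int = 32
    roi_fg_fraction: float = 0.5
    roi_fg_iou: float = 0.5
    seed: int = 0

    @property
    def total_iterations(self) -> int:
        if self.iterations is not None:
            return self.iterations
        return self.iterations_per_epoch * self.epochs


@dataclass
class TrainResult:
    loss_log: list[dict] = field(default_factory=list)
    config: TrainConfig | None = None


def _sample_rois(
    proposals: np.ndarray,
    gt_boxes: np.ndarray,
    gt_labels: np.ndarray,
    rng: np.random.Generator,
    cfg: TrainConfig,
):
    """Sample foreground/background RoIs for the head from proposals + gt boxes.

    Ground-truth boxes and randomly jittered copies of them are appended to
    the RPN proposals so the head sees both exact and imperfect foreground
    RoIs and learns to refine the latter.
    """
    if len(gt_boxes):
        jittered = []
        for _ in range(3):
            w = gt_boxes[:, 2] - gt_boxes[:, 0]
            h = gt_boxes[:, 3] - gt_boxes[:, 1]
            dx = rng.uniform(-0.15, 0.15, len(gt_boxes)) * w
            dy = rng.uniform(-0.15, 0.15, len(gt_boxes)) * h
            ds = rng.uniform(0.85, 1.18, (len(gt_boxes), 2))
            cx = (gt_boxes[:, 0] + gt_boxes[:, 2]) / 2 + dx
            cy = (gt_boxes[:, 1] + gt_boxes[:, 3]) / 2 + dy
            nw, nh = np.maximum(w * ds[:, 0], 2), np.maximum(h * ds[:, 1], 2)
            jittered.append(
                np.stack([cx - nw / 2, cy - nh / 2, cx + nw / 2, cy + nh / 2], axis=1)
            )
        rois = np.concatenate([proposals, gt_boxes] + jittered, axis=0)
    else:
        rois = proposals
    iou = iou_matrix(rois, gt_boxes)
    best = iou.argmax(axis=1) if iou.shape[1] else np.zeros(len(rois), dtype=int)
    best_iou = iou.max(axis=1) if iou.shape[1] else np.zeros(len(rois))
    fg = np.nonzero(best_iou >= cfg.roi_fg_iou)[0]
    bg = np.nonzero(best_iou < cfg.roi_fg_iou)[0]
    n_fg = min(len(fg), int(cfg.roi_batch_size * cfg.roi_fg_fraction))
    if len(fg) > n_fg:
        fg = rng.choice(fg, size=n_fg, replace=False)
    n_bg = min(len(bg), cfg.roi_batch_size - n_fg)
    if len(bg) > n_bg:
        bg = rng.choice(bg, size=n_bg, replace=False)
    keep = np.concatenate([fg, bg]).astype(int)
    labels = np.zeros(len(keep), dtype=int)  # 0 = background
    labels[: len(fg)] = gt_labels[best[fg]] + 1
    targets = np.zeros((len(keep), 4))
    if len(fg):
        from .network import HEAD_DELTA_STD

        targets[: len(fg)] = encode_box_deltas(gt_boxes[best[fg]], rois[fg]) / HEAD_DELTA_STD
    return rois[keep], labels, targets


def _head_loss(head, feature, rois, labels, targets, stride) -> tuple[Tensor, float, float]:
    cls_logits, reg = head(feature, rois / stride)
    n = max(len(labels), 1)
    cls_term = nn.softmax_cross_entropy(cls_logits, labels) * Tensor(np.float32(1.0 / n))
    fg = np.nonzero(labels > 0)[0]
    reg_term = Tensor(np.float32(0.0))
    if len(fg):
        n_cls = len(CLASS_NAMES) + 1
        reg_r = reg.reshape(len(labels), n_cls, 4)
        flat = reg_r.reshape(len(labels) * n_cls, 4)
        sel = fg * n_cls + labels[fg]
        pred = nn.gather_rows(flat, sel)
        reg_term = nn.smooth_l1_loss(pred, targets[fg]) * Tensor(np.float32(1.0 / n))
    total = cls_term + reg_term
    return total, float(cls_term.data), float(reg_term.data)


def train(
    dataset: list[tuple[np.ndarray, np.ndarray, AnnotationSet]],
    net: WeedDetectionNet | None = None,
    config: TrainConfig | None = None,
    net_config: NetworkConfig | None = None,
    callback=None,
) -> tuple[WeedDetectionNet, TrainResult]:
    """Train the detector on ``(rgb, pha, annotations)`` triples.

    Fully seedable: identical ``config.seed`` and dataset give identical
    loss logs and weights.  Aborts with ``FloatingPointError`` if the loss
    diverges to a non-finite value.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    config = config or TrainConfig()
    if net is None:
        net = WeedDetectionNet(net_config or NetworkConfig(), seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.SGD(
        net.parameters(),
        lr=config.initial_learning_rate,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    label_of = {name: i for i, name in enumerate(CLASS_NAMES)}
    result = TrainResult(config=config)

    for it in range(config.total_iterations):
        rgb, pha, anns = dataset[int(rng.integers(len(dataset)))]
        image_size = rgb.shape[:2]
        gt_boxes = anns.boxes()
        gt_labels = np.array([label_of[lab] for lab in anns.labels()], dtype=int)

        feats = net.branch_features(rgb, pha)
        losses: list[Tensor] = []
        log = {"iteration": it}
        for branch in net.BRANCHES:
            batch, logits, deltas, anchors = net.rpn_supervision(
                branch, feats[branch], gt_boxes, image_size, rng
            )
            l_rpn, l_cls, l_reg = rpn_loss(batch, logits, deltas)
            losses.append(l_rpn)
            log[f"rpn_{branch}_cls"] = l_cls
            log[f"rpn_{branch}_reg"] = l_reg

            stride = 4 if branch == "corr" else 16
            scores = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
            boxes = clip_boxes(decode_box_deltas(deltas.data.astype(np.float64), anchors), image_size)
            ok = (boxes[:, 2] - boxes[:, 0] >= 1) & (boxes[:, 3] - boxes[:, 1] >= 1)
            order = np.argsort(-scores, kind="stable")
            order = order[ok[order]][: net.config.pre_nms_top]
            keep = _nms(boxes[order], scores[order], net.config.proposal_nms_iou)
            proposals = boxes[order[keep[: net.config.post_nms_top]]]

            rois, roi_labels, roi_targets = _sample_rois(
                proposals, gt_boxes, gt_labels, rng, config
            )
            if len(rois):
                head = {"rgb": net.head_rgb, "pha": net.head_pha, "corr": net.head_corr}[branch]
                l_head, h_cls, h_reg = _head_loss(
                    head, feats[branch], rois, roi_labels, roi_targets, stride
                )
                losses.append(l_head)
                log[f"head_{branch}_cls"] = h_cls
                log[f"head_{branch}_reg"] = h_reg

        total = losses[0]
        for l in losses[1:]:
            total = total + l
        log["total"] = float(total.data)
        if not np.isfinite(log["total"]):
            raise FloatingPointError(
                f"training diverged at iteration {it}: loss = {log['total']}"
            )
        opt.zero_grad()
        total.backward()
        opt.step()
        result.loss_log.append(log)
        if callback is not None:
            callback(it, log)
    return net, result


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(net: WeedDetectionNet, path: str | Path, train_config: TrainConfig | None = None) -> None:
    """Single-file archive: named parameter groups plus a config echo."""
    meta = {
        "backbone_variant": net.config.backbone.variant,
        "weight_sharing": net.config.weight_sharing,
        "hyper_channels": net.config.backbone.hyper_channels,
        "train_config": asdict(train_config) if train_config else None,
    }
    state = net.state_dict()
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path: str | Path, net_config: NetworkConfig | None = None) -> WeedDetectionNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if net_config is None:
        from .network import BackboneConfig

        net_config = NetworkConfig(
            backbone=BackboneConfig(variant=meta["backbone_variant"]),
            weight_sharing=meta["weight_sharing"],
        )
    net = WeedDetectionNet(net_config, seed=0)
    net.load_state_dict(state)
    return net
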