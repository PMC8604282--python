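"""Three-branch multi-modal weed detection network.

Two branches learn modality-specific features from the RGB image and the
PHA recoding of depth; a third, *correlated* branch learns joint RGB-D
features.  All branches share the two-stage detector design (region
proposal network over anchors, then an RoI head refining class scores and
boxes):

* The RGB- and PHA-specific branches detect from their backbone's final
  (stride-16) feature map.
* The correlated branch builds a multiscale *hyper feature* per modality
  by resampling the feature maps after backbone blocks 1, 3 and 5 to the
  block-3 (stride-4) resolution — max pooling the shallow map, learned
  4x deconvolution for the deep map — concatenating, normalising and
  projecting with a 1x1 convolution; the two modalities' hyper features
  are then fused with an elementwise (Hadamard) product.
* The RGB and PHA backbones share weights by default: one set of filters
  serves both modalities, halving the parameter count.

The backbone is configurable: ``vgg16`` reproduces the classic 13-layer
convolutional stack, ``tiny`` keeps the 5-block stride pattern
(1, 2, 4, 8, 16) at a width that trains in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .anchors import AnchorConfig, build_rpn_batch, generate_anchors, RPNTrainingBatch
from .boxes import clip_boxes, decode_box_deltas, encode_box_deltas, nms
from .detections import DetectionSet
from .nn import Tensor
from .rgbd_io import CLASS_NAMES

__all__ = [
    "BackboneConfig",
    "NetworkConfig",
    "Backbone",
    "HyperFeature",
    "hadamard_fuse",
    "RPNHead",
    "RoIHead",
    "WeedDetectionNet",
    "rpn_loss",
]

_EPS = 1e-5

#: Box-delta normalisation for the RoI head: encoded targets are divided by
#: these standard deviations during training and predictions multiplied back
#: at inference, so the regression outputs live at unit scale.
HEAD_DELTA_STD = np.array([0.1, 0.1, 0.2, 0.2])


@dataclass
class BackboneConfig:
    """Five conv blocks with stride-2 pooling after blocks 1-4."""

    variant: str = "tiny"
    blocks: tuple[tuple[int, ...], ...] = ()
    hyper_channels: int = 0

    def __post_init__(self) -> None:
        presets = {
            "tiny": (((8,), (16,), (16,), (24,), (32,)), 24),
            "vgg16": (
                ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512)),
                126,
            ),
        }
        if not self.blocks:
            if self.variant not in presets:
                raise ValueError(f"unknown backbone variant {self.variant!r}")
            self.blocks, default_c = presets[self.variant]
            if not self.hyper_channels:
                self.hyper_channels = default_c
        if len(self.blocks) != 5:
            raise ValueError("backbone must have exactly 5 blocks")


@dataclass
class NetworkConfig:
    """Everything that shapes the detector besides learned weights."""

    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    weight_sharing: bool = True
    rpn_mid_channels: int = 24
    roi_hidden: int = 64
    roi_pool_size: int = 7
    # anchors: specific branches sit at stride 16, the correlated branch at 4
    anchors_specific: AnchorConfig = field(
        default_factory=lambda: AnchorConfig(scales=(16.0, 28.0, 44.0), ratios=(0.33, 1.0, 3.0))
    )
    anchors_corr: AnchorConfig = field(
        default_factory=lambda: AnchorConfig(scales=(12.0, 24.0, 40.0), ratios=(0.33, 1.0, 3.0))
    )
    proposal_nms_iou: float = 0.7  # NMS threshold applied to RPN proposals
    pre_nms_top: int = 256
    post_nms_top: int = 32
    final_nms_iou: float = 0.3
    score_threshold: float = 0.05
    max_per_class: int = 20
    rpn_lambda: float = 10.0
    rpn_batch_size: int = 256

    def scaled_for(self, image_size: int) -> "NetworkConfig":
        """Anchor scales proportionally shrunk for small test images."""
        if image_size >= 256:
            return self
        s = image_size / 256.0
        return replace(
            self,
            anchors_specific=AnchorConfig(
                scales=tuple(max(4.0, v * s * 2) for v in self.anchors_specific.scales),
                ratios=self.anchors_specific.ratios,
            ),
            anchors_corr=AnchorConfig(
                scales=tuple(max(4.0, v * s * 2) for v in self.anchors_corr.scales),
                ratios=self.anchors_corr.ratios,
            ),
            # smaller anchor mini-batch: a tiny image yields only a handful
            # of positive anchors, so a 256-sample batch would be nearly
            # all background
            rpn_batch_size=32,
        )


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class Backbone(nn.Module):
    """Five conv blocks; returns the feature map after each block.

    Block outputs sit at strides 1, 2, 4, 8, 16 relative to the input
    (2x2 max pooling after blocks 1-4).
    """

    def __init__(self, rng: np.random.Generator, config: BackboneConfig):
        self.config = config
        self.blocks = []
        in_ch = 3
        for spec in config.blocks:
            layers = []
            for out_ch in spec:
                layers.append(nn.Conv2d(rng, in_ch, out_ch, k=3))
                layers.append(nn.ReLU())
                in_ch = out_ch
            self.blocks.append(nn.Sequential(*layers))

    @property
    def out_channels(self) -> tuple[int, ...]:
        return tuple(spec[-1] for spec in self.config.blocks)

    def __call__(self, x: Tensor) -> list[Tensor]:
        feats = []
        for i, block in enumerate(self.blocks):
            x = block(x)
            feats.append(x)
            if i < 4:
                x = nn.maxpool2d(x, 2)
        return feats


def _channel_norm(x: Tensor) -> Tensor:
    """Per-location response normalisation across channels (L2-style)."""
    m = (x * x).mean_axis(1, keepdims=True)
    inv = (m + Tensor(np.float32(_EPS))).pow_const(-0.5)
    return x * inv


class HyperFeature(nn.Module):
    """Multiscale fusion of block-1, block-3 and block-5 feature maps.

    The shallow map is max-pooled 4x down, the deep map deconvolved 4x up,
    both to the block-3 resolution (stride 4); the three are concatenated,
    response-normalised and projected to ``hyper_channels`` by a learned
    1x1 convolution.
    """

    def __init__(self, rng: np.random.Generator, c1: int, c3: int, c5: int, out_channels: int):
        self.deconv = nn.ConvTranspose2d(rng, c5, c5, stride=4)
        self.project = nn.Conv2d(rng, c1 + c3 + c5, out_channels, k=1, pad=0)

    def __call__(self, f1: Tensor, f3: Tensor, f5: Tensor) -> Tensor:
        a = nn.maxpool2d(f1, 4)
        c = self.deconv(f5)
        for name, t in (("block1", a), ("block5", c)):
            if t.shape[2:] != f3.shape[2:]:
                raise ValueError(
                    f"hyper-feature shape mismatch: {name} resampled to {t.shape[2:]}, "
                    f"block3 is {f3.shape[2:]}"
                )
        fused = nn.concat([a, f3, c], axis=1)
        # linear projection: a ReLU here would zero half of each modality's
        # hyper feature and the downstream Hadamard product of two sparse
        # maps would be almost everywhere zero
        return self.project(_channel_norm(fused))


def hadamard_fuse(f_a: Tensor, f_b: Tensor) -> Tensor:
    """Cross-modal fusion: strict elementwise (Hadamard) product."""
    if f_a.shape != f_b.shape:
        raise ValueError(f"shape mismatch: {f_a.shape} vs {f_b.shape}")
    return f_a * f_b


class RPNHead(nn.Module):
    """Sliding 3x3 conv predicting objectness and box deltas per anchor."""

    def __init__(self, rng: np.random.Generator, in_channels: int, mid_channels: int, n_anchors: int):
        self.n_anchors = n_anchors
        self.conv = nn.Conv2d(rng, in_channels, mid_channels, k=3)
        self.cls = nn.Conv2d(rng, mid_channels, n_anchors, k=1, pad=0)
        self.reg = nn.Conv2d(rng, mid_channels, 4 * n_anchors, k=1, pad=0)
        # prediction-layer init: tiny weights so early proposals coincide
        # with their anchors, and a negative objectness bias
        # (sigmoid(-2) ~ 0.12) matching the background-dominated prior
        self.cls.weight.data *= 0.05
        self.cls.bias.data[:] = -2.0
        self.reg.weight.data *= 0.05

    def __call__(self, feature: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (objectness logits (HWA,), deltas (HWA, 4)), cell-major order."""
        h = nn.relu(self.conv(feature))
        logits = self.cls(h)  # (1, A, H, W)
        deltas = self.reg(h)  # (1, 4A, H, W)
        a = self.n_anchors
        _, _, fh, fw = logits.shape
        logits = logits.transpose((0, 2, 3, 1)).reshape(fh * fw * a)
        deltas = deltas.reshape(1, a, 4, fh, fw).transpose((0, 3, 4, 1, 2)).reshape(fh * fw * a, 4)
        return logits, deltas


class RoIHead(nn.Module):
    """7x7 RoI pooling, two hidden layers, softmax classes + class-wise boxes."""

    def __init__(self, rng: np.random.Generator, in_channels: int, hidden: int, pool: int = 7):
        self.pool = pool
        self.in_channels = in_channels
        n_cls = len(CLASS_NAMES) + 1  # + background
        self.fc1 = nn.Linear(rng, in_channels * pool * pool, hidden)
        self.fc2 = nn.Linear(rng, hidden, hidden)
        self.cls = nn.Linear(rng, hidden, n_cls)
        self.reg = nn.Linear(rng, hidden, 4 * n_cls)
        # tiny prediction-layer init: refined boxes start at their RoIs
        self.cls.weight.data *= 0.1
        self.reg.weight.data *= 0.05

    def __call__(self, feature: Tensor, rois: np.ndarray) -> tuple[Tensor, Tensor]:
        pooled = nn.roi_pool(feature, rois, self.pool)
        flat = pooled.reshape(rois.shape[0], self.in_channels * self.pool * self.pool)
        h = nn.relu(self.fc2(nn.relu(self.fc1(flat))))
        return self.cls(h), self.reg(h)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def rpn_loss(
    batch: RPNTrainingBatch, logits: Tensor, deltas: Tensor
) -> tuple[Tensor, float, float]:
    """Multi-task RPN loss.

    ``L = (1/N_cls) sum_i L_cls(p_i, p_i*) + lambda (1/N_reg) sum_i p_i* .
    SmoothL1(t_i - t_i*)`` with log loss for the classification term,
    normalised by the sampled mini-batch size, and the regression term
    summed over positive anchors only and normalised by the number of
    anchor locations.  Returns the loss tensor plus the two raw terms for
    logging.
    """
    idx = batch.sample_idx
    cls_term = Tensor(np.float32(0.0))
    if len(idx):
        sampled_logits = nn.gather_rows(logits.reshape(-1, 1), idx).reshape(len(idx))
        targets = (batch.labels[idx] == 1).astype(np.float32)
        cls_term = nn.bce_with_logits(sampled_logits, targets) * Tensor(
            np.float32(1.0 / batch.n_cls)
        )
    pos = np.nonzero(batch.labels[idx] == 1)[0] if len(idx) else np.zeros(0, dtype=int)
    pos_idx = idx[pos]
    reg_term = Tensor(np.float32(0.0))
    if len(pos_idx):
        pred = nn.gather_rows(deltas, pos_idx)
        reg_term = nn.smooth_l1_loss(pred, batch.target_deltas[pos_idx]) * Tensor(
            np.float32(batch.lam / batch.n_reg)
        )
    total = cls_term + reg_term
    return total, float(cls_term.data), float(reg_term.data)


# ---------------------------------------------------------------------------
# the full detector
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class WeedDetectionNet(nn.Module):
    """The assembled three-branch detector.

    Branch layout (``branch`` in {"rgb", "pha", "corr"}):

    ====== ==================== ====== =============================
    branch feature              stride anchors
    ====== ==================== ====== =============================
    rgb    RGB block-5 map      16     ``anchors_specific``
    pha    PHA block-5 map      16     ``anchors_specific``
    corr   Hadamard of hyper    4      ``anchors_corr``
    ====== ==================== ====== =============================
    """

    BRANCHES = ("rgb", "pha", "corr")

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        rng = np.random.default_rng(seed)
        bb_cfg = self.config.backbone
        self.backbone_rgb = Backbone(rng, bb_cfg)
        if self.config.weight_sharing:
            # the PHA stream runs through the *same object*: one parameter
            # set serves both modalities and updates coincide by construction
            self.backbone_pha = self.backbone_rgb
        else:
            self.backbone_pha = Backbone(rng, bb_cfg)
        c1, _, c3, _, c5 = self.backbone_rgb.out_channels
        ch = bb_cfg.hyper_channels
        self.hyper = HyperFeature(rng, c1, c3, c5, ch)
        mid = self.config.rpn_mid_channels
        self.rpn_rgb = RPNHead(rng, c5, mid, self.config.anchors_specific.per_cell)
        self.rpn_pha = RPNHead(rng, c5, mid, self.config.anchors_specific.per_cell)
        self.rpn_corr = RPNHead(rng, ch, mid, self.config.anchors_corr.per_cell)
        self.head_rgb = RoIHead(rng, c5, self.config.roi_hidden, self.config.roi_pool_size)
        self.head_pha = RoIHead(rng, c5, self.config.roi_hidden, self.config.roi_pool_size)
        self.head_corr = RoIHead(rng, ch, self.config.roi_hidden, self.config.roi_pool_size)

    # -- plumbing -----------------------------------------------------------

    @staticmethod
    def _to_tensor(raster: np.ndarray) -> Tensor:
        arr = np.asarray(raster)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) raster")
        x = (arr.astype(np.float32) / 255.0 - 0.5) / 0.25
        return Tensor(x.transpose(2, 0, 1)[None])

    def branch_features(self, rgb: np.ndarray, pha: np.ndarray) -> dict[str, Tensor]:
        """Run both backbones and assemble the three branch feature maps."""
        if rgb.shape[:2] != pha.shape[:2]:
            raise ValueError(
                f"RGB and PHA rasters must be co-registered and equal-size: "
                f"{rgb.shape[:2]} vs {pha.shape[:2]}"
            )
        feats_rgb = self.backbone_rgb(self._to_tensor(rgb))
        feats_pha = self.backbone_pha(self._to_tensor(pha))
        hyper_rgb = self.hyper(feats_rgb[0], feats_rgb[2], feats_rgb[4])
        hyper_pha = self.hyper(feats_pha[0], feats_pha[2], feats_pha[4])
        # renormalise after the product: elementwise multiplication squares
        # the dynamic range, which would otherwise destabilise the corr RPN
        return {
            "rgb": feats_rgb[4],
            "pha": feats_pha[4],
            "corr": _channel_norm(hadamard_fuse(hyper_rgb, hyper_pha)),
        }

    def _branch_parts(self, branch: str):
        stride = 4 if branch == "corr" else 16
        anchor_cfg = self.config.anchors_corr if branch == "corr" else self.config.anchors_specific
        rpn = {"rgb": self.rpn_rgb, "pha": self.rpn_pha, "corr": self.rpn_corr}[branch]
        head = {"rgb": self.head_rgb, "pha": self.head_pha, "corr": self.head_corr}[branch]
        return stride, anchor_cfg, rpn, head

    def propose(
        self, branch: str, feature: Tensor, image_size: tuple[int, int]
    ) -> tuple[np.ndarray, np.ndarray, Tensor, Tensor, np.ndarray]:
        """RPN forward for one branch: proposals after score ranking and NMS.

        Returns ``(proposals, proposal_scores, logits, deltas, anchors)``;
        the logits/deltas tensors keep the gradient tape for training.
        """
        stride, anchor_cfg, rpn, _ = self._branch_parts(branch)
        logits, deltas = rpn(feature)
        fh, fw = feature.shape[2], feature.shape[3]
        anchors = generate_anchors((fh, fw), stride, anchor_cfg)
        scores = _sigmoid(logits.data.astype(np.float64))
        boxes = clip_boxes(decode_box_deltas(deltas.data.astype(np.float64), anchors), image_size)
        wh_ok = (boxes[:, 2] - boxes[:, 0] >= 1) & (boxes[:, 3] - boxes[:, 1] >= 1)
        order = np.argsort(-scores, kind="stable")
        order = order[wh_ok[order]][: self.config.pre_nms_top]
        keep = nms(boxes[order], scores[order], self.config.proposal_nms_iou)
        keep = order[keep[: self.config.post_nms_top]]
        return boxes[keep], scores[keep], logits, deltas, anchors

    def detect_branch(
        self, branch: str, feature: Tensor, image_size: tuple[int, int]
    ) -> DetectionSet:
        """Full inference for one branch: proposals -> RoI head -> per-class NMS."""
        stride, _, _, head = self._branch_parts(branch)
        proposals, _, _, _, _ = self.propose(branch, feature, image_size)
        if proposals.shape[0] == 0:
            return DetectionSet(source=branch)
        cls_logits, reg = head(feature, proposals / stride)
        probs = _softmax(cls_logits.data.astype(np.float64))
        reg = reg.data.astype(np.float64).reshape(-1, len(CLASS_NAMES) + 1, 4)
        reg = reg * HEAD_DELTA_STD[None, None, :]
        all_boxes, all_scores, all_labels = [], [], []
        for ci, cname in enumerate(CLASS_NAMES, start=1):
            scores = probs[:, ci]
            boxes = clip_boxes(decode_box_deltas(reg[:, ci, :], proposals), image_size)
            ok = (
                (scores >= self.config.score_threshold)
                & (boxes[:, 2] - boxes[:, 0] >= 1)
                & (boxes[:, 3] - boxes[:, 1] >= 1)
            )
            boxes, scores = boxes[ok], scores[ok]
            keep = nms(boxes, scores, self.config.final_nms_iou)[: self.config.max_per_class]
            all_boxes.append(boxes[keep])
            all_scores.append(scores[keep])
            all_labels.extend([cname] * len(keep))
        boxes = np.concatenate(all_boxes) if all_boxes else np.zeros((0, 4))
        scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
        return DetectionSet(boxes, scores, all_labels, source=branch).sort()

    def forward(self, rgb: np.ndarray, pha: np.ndarray) -> dict[str, DetectionSet]:
        """Detect weeds in one co-registered RGB / PHA pair.

        Deterministic in eval: identical inputs give identical outputs.
        """
        image_size = rgb.shape[:2]
        feats = self.branch_features(rgb, pha)
        return {b: self.detect_branch(b, feats[b], image_size) for b in self.BRANCHES}

    __call__ = forward

    # -- training-side helpers (used by weedspot.training) ------------------

    def rpn_supervision(
        self,
        branch: str,
        feature: Tensor,
        gt_boxes: np.ndarray,
        image_size: tuple[int, int],
        rng: np.random.Generator,
    ) -> tuple[RPNTrainingBatch, Tensor, Tensor, np.ndarray]:
        stride, anchor_cfg, rpn, _ = self._branch_parts(branch)
        logits, deltas = rpn(feature)
        fh, fw = feature.shape[2], feature.shape[3]
        anchors = generate_anchors((fh, fw), stride, anchor_cfg)
        batch = build_rpn_batch(
            anchors,
            gt_boxes,
            rng,
            batch_size=self.config.rpn_batch_size,
            lam=self.config.rpn_lambda,
        )
        return batch, logits, deltas, anchors
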