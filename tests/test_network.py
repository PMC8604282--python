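"""Detection network: fusion ops, anchor assignment, RPN loss, training dynamics."""

import numpy as np
import pytest

from weedspot import nn
from weedspot.anchors import (
    AnchorConfig,
    RPNTrainingBatch,
    assign_anchor_labels,
    generate_anchors,
)
from weedspot.boxes import smooth_l1
from weedspot.network import (
    BackboneConfig,
    HyperFeature,
    NetworkConfig,
    WeedDetectionNet,
    hadamard_fuse,
    rpn_loss,
)
from weedspot.nn import Tensor
from weedspot.training import TrainConfig, load_checkpoint, save_checkpoint, train


class TestHyperFeature:
    def test_output_at_quarter_resolution(self, rng):
        hf = HyperFeature(rng, c1=4, c3=6, c5=8, out_channels=12)
        f1 = Tensor(rng.standard_normal((1, 4, 64, 64)))
        f3 = Tensor(rng.standard_normal((1, 6, 16, 16)))
        f5 = Tensor(rng.standard_normal((1, 8, 4, 4)))
        assert hf(f1, f3, f5).shape == (1, 12, 16, 16)

    def test_shape_mismatch_is_hard_error(self, rng):
        hf = HyperFeature(rng, 4, 6, 8, 12)
        f1 = Tensor(rng.standard_normal((1, 4, 64, 64)))
        f3 = Tensor(rng.standard_normal((1, 6, 15, 15)))  # not stride-4 of 64
        f5 = Tensor(rng.standard_normal((1, 8, 4, 4)))
        with pytest.raises(ValueError, match="hyper-feature shape mismatch"):
            hf(f1, f3, f5)

    def test_backbone_stride_pattern(self, rng):
        from weedspot.network import Backbone

        bb = Backbone(rng, BackboneConfig(variant="tiny"))
        feats = bb(Tensor(rng.standard_normal((1, 3, 64, 64))))
        assert [f.shape[2] for f in feats] == [64, 32, 16, 8, 4]


class TestHadamard:
    def test_multiplicative_identity(self, rng):
        f = Tensor(rng.standard_normal((1, 4, 8, 8)))
        ones = Tensor(np.ones((1, 4, 8, 8)))
        np.testing.assert_array_equal(hadamard_fuse(f, ones).data, f.data)

    def test_zero_annihilates(self, rng):
        f = Tensor(rng.standard_normal((1, 4, 8, 8)))
        z = Tensor(np.zeros((1, 4, 8, 8)))
        assert np.all(hadamard_fuse(f, z).data == 0)

    def test_matches_scalar_loop_oracle_exactly(self, rng):
        a = rng.standard_normal((1, 3, 5, 5)).astype(np.float32)
        b = rng.standard_normal((1, 3, 5, 5)).astype(np.float32)
        got = hadamard_fuse(Tensor(a), Tensor(b)).data
        want = np.empty_like(a)
        for c in range(3):
            for i in range(5):
                for j in range(5):
                    want[0, c, i, j] = a[0, c, i, j] * b[0, c, i, j]
        np.testing.assert_array_equal(got, want)

    def test_commutative(self, rng):
        a = Tensor(rng.standard_normal((1, 2, 4, 4)))
        b = Tensor(rng.standard_normal((1, 2, 4, 4)))
        np.testing.assert_array_equal(hadamard_fuse(a, b).data, hadamard_fuse(b, a).data)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape mismatch"):
            hadamard_fuse(
                Tensor(rng.standard_normal((1, 2, 4, 4))),
                Tensor(rng.standard_normal((1, 2, 5, 5))),
            )


class TestAnchorAssignment:
    CFG = AnchorConfig(scales=(8.0, 16.0), ratios=(1.0,))

    def test_perfect_overlap_positive(self):
        anchors = generate_anchors((4, 4), 16, self.CFG)
        gt = anchors[5:6].copy()
        labels, matched = assign_anchor_labels(anchors, gt)
        assert labels[5] == 1 and matched[5] == 0

    def test_low_iou_gt_still_gets_its_best_anchor(self):
        anchors = generate_anchors((4, 4), 16, self.CFG)
        gt = np.array([[1.0, 1.0, 6.0, 6.0]])  # max IoU with any anchor < 0.7
        labels, matched = assign_anchor_labels(anchors, gt)
        from weedspot.boxes import iou_matrix

        iou = iou_matrix(anchors, gt)[:, 0]
        assert iou.max() < 0.7
        assert np.all(labels[iou == iou.max()] == 1)

    def test_disjoint_anchor_negative(self):
        anchors = np.array([[0, 0, 10, 10.0], [100, 100, 120, 120.0]])
        labels, _ = assign_anchor_labels(anchors, np.array([[0, 0, 10, 10.0]]))
        assert labels[1] == 0

    def test_no_gt_all_negative(self):
        anchors = generate_anchors((2, 2), 16, self.CFG)
        labels, _ = assign_anchor_labels(anchors, np.zeros((0, 4)))
        assert np.all(labels == 0)

    def test_every_gt_has_a_positive_anchor(self, rng):
        anchors = generate_anchors((8, 8), 8, AnchorConfig((8.0, 16.0, 32.0), (0.5, 1.0, 2.0)))
        for _ in range(20):
            gt = np.stack(
                [
                    rng.uniform(0, 40, 3),
                    rng.uniform(0, 40, 3),
                    np.zeros(3),
                    np.zeros(3),
                ],
                axis=1,
            )
            gt[:, 2] = gt[:, 0] + rng.uniform(4, 24, 3)
            gt[:, 3] = gt[:, 1] + rng.uniform(4, 24, 3)
            labels, matched = assign_anchor_labels(anchors, gt)
            assert set(matched[labels == 1]) == set(range(3))


class TestRPNLoss:
    def _batch_and_preds(self):
        """Hand-built 4-anchor batch with known labels, targets, predictions."""
        labels = np.array([1, 0, 1, 0])
        targets = np.zeros((4, 4))
        targets[0] = [0.1, -0.2, 0.3, 0.0]
        targets[2] = [-0.5, 0.4, 0.0, 2.0]
        batch = RPNTrainingBatch(
            labels=labels,
            target_deltas=targets,
            matched_gt=np.zeros(4, dtype=int),
            n_cls=4,
            n_reg=4,
            lam=10.0,
            sample_idx=np.arange(4),
        )
        logits = Tensor(np.array([2.0, -1.0, 0.5, -3.0], dtype=np.float32), requires_grad=True)
        deltas = Tensor(
            np.array(
                [[0.0, 0.0, 0.0, 0.0], [9.0, 9.0, 9.0, 9.0], [-0.5, 0.4, 0.2, 0.5], [0, 0, 0, 0]],
                dtype=np.float32,
            ),
            requires_grad=True,
        )
        return batch, logits, deltas

    def test_matches_scalar_loop_oracle(self):
        batch, logits, deltas = self._batch_and_preds()
        total, _, _ = rpn_loss(batch, logits, deltas)
        # independent scalar-loop computation
        z = logits.data.astype(float)
        t = (batch.labels == 1).astype(float)
        cls = 0.0
        for i in range(4):
            p = 1 / (1 + np.exp(-z[i]))
            cls += -(t[i] * np.log(p) + (1 - t[i]) * np.log(1 - p))
        cls /= batch.n_cls
        reg = 0.0
        for i in range(4):
            if batch.labels[i] == 1:
                for d in range(4):
                    reg += smooth_l1(deltas.data[i, d] - batch.target_deltas[i, d])
        reg *= batch.lam / batch.n_reg
        assert float(total.data) == pytest.approx(cls + reg, abs=1e-6)

    def test_lambda_zero_decouples_regression(self):
        batch, logits, deltas = self._batch_and_preds()
        batch.lam = 0.0
        total, cls, reg = rpn_loss(batch, logits, deltas)
        assert reg == 0.0
        assert float(total.data) == pytest.approx(cls)

    def test_perfect_predictions_approach_zero(self):
        batch, logits, deltas = self._batch_and_preds()
        logits.data = np.where(batch.labels == 1, 20.0, -20.0).astype(np.float32)
        deltas.data = batch.target_deltas.astype(np.float32)
        total, cls, reg = rpn_loss(batch, logits, deltas)
        assert reg == 0.0
        assert cls < 1e-6

    def test_empty_positive_set_zero_regression(self):
        batch, logits, deltas = self._batch_and_preds()
        batch.labels[:] = 0
        _, _, reg = rpn_loss(batch, logits, deltas)
        assert reg == 0.0


class TestForward:
    def test_untrained_contract_and_determinism(self, rng):
        net = WeedDetectionNet(NetworkConfig().scaled_for(64), seed=3)
        rgb = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        pha = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        out1 = net(rgb, pha)
        out2 = net(rgb, pha)
        assert set(out1) == {"rgb", "pha", "corr"}
        for b, ds in out1.items():
            assert ds.source == b
            assert np.all(ds.scores >= 0) and np.all(ds.scores <= 1)
            assert np.all(ds.boxes[:, 2] <= 64) and np.all(ds.boxes[:, 0] >= 0)
            np.testing.assert_array_equal(ds.boxes, out2[b].boxes)

    def test_unregistered_sizes_rejected(self, rng):
        net = WeedDetectionNet(NetworkConfig().scaled_for(64), seed=3)
        rgb = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        pha = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="co-registered"):
            net(rgb, pha)

    def test_weight_sharing_is_object_identity(self):
        net = WeedDetectionNet(NetworkConfig(weight_sharing=True), seed=0)
        assert net.backbone_rgb is net.backbone_pha
        unshared = WeedDetectionNet(NetworkConfig(weight_sharing=False), seed=0)
        assert unshared.backbone_rgb is not unshared.backbone_pha
        # shared parameters are counted once
        assert len(net.parameters()) < len(unshared.parameters())


class TestTraining:
    def test_zero_learning_rate_is_null_step(self, tiny_dataset):
        pairs, _ = tiny_dataset
        cfg = NetworkConfig().scaled_for(64)
        net = WeedDetectionNet(cfg, seed=1)
        before = {k: v.copy() for k, v in net.state_dict().items()}
        net, _ = train(
            pairs[:2], net=net, config=TrainConfig(iterations=1, initial_learning_rate=0.0, seed=0)
        )
        after = net.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_loss_decreases_over_fifty_steps(self, tiny_dataset):
        pairs, _ = tiny_dataset
        net, result = train(
            pairs[:2],
            net_config=NetworkConfig().scaled_for(64),
            config=TrainConfig(iterations=50, seed=0),
        )
        first = np.mean([l["total"] for l in result.loss_log[:5]])
        last = np.mean([l["total"] for l in result.loss_log[-5:]])
        assert last < first

    def test_same_seed_identical_loss_logs(self, tiny_dataset):
        pairs, _ = tiny_dataset
        cfg = NetworkConfig().scaled_for(64)
        _, r1 = train(pairs[:2], net_config=cfg, config=TrainConfig(iterations=10, seed=5))
        _, r2 = train(pairs[:2], net_config=cfg, config=TrainConfig(iterations=10, seed=5))
        assert [l["total"] for l in r1.loss_log] == [l["total"] for l in r2.loss_log]

    def test_checkpoint_roundtrip_preserves_outputs(self, tiny_dataset, tmp_path):
        pairs, _ = tiny_dataset
        cfg = NetworkConfig().scaled_for(64)
        net, _ = train(pairs[:2], net_config=cfg, config=TrainConfig(iterations=5, seed=2))
        path = tmp_path / "w.npz"
        save_checkpoint(net, path)
        net2 = load_checkpoint(path, cfg)
        rgb, pha, _ = pairs[0]
        o1, o2 = net(rgb, pha), net2(rgb, pha)
        for b in o1:
            np.testing.assert_array_equal(o1[b].boxes, o2[b].boxes)
            np.testing.assert_array_equal(o1[b].scores, o2[b].scores)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], config=TrainConfig(iterations=1))
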