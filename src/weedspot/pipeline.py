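"""End-to-end pipeline: generate -> recode -> train -> detect -> ensemble -> evaluate.

Every stage reads and writes only open interchange formats (PNG, VOC XML,
YAML, JSONL, JSON, npz weights), so each is resumable and inspectable: a
rerun with ``resume=True`` skips stages whose outputs already exist.  All
randomness flows from the single top-level seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .camera import CameraRig
from .detections import DetectionSet, read_detections_jsonl, write_detections_jsonl
from .ensemble import EnsembleWeights, fuse_detections
from .evaluation import evaluate
from .network import BackboneConfig, NetworkConfig, WeedDetectionNet
from .pha import RecodeParams, recode_to_pha
from .rgbd_io import (
    fill_holes,
    read_color,
    read_depth_png,
    read_voc_annotations,
    write_color_png,
    write_depth_png,
    write_voc_annotations,
)
from .synthetic import SceneConfig, generate_scene
from .training import TrainConfig, load_checkpoint, save_checkpoint, train

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("generate", "recode", "train", "detect", "ensemble", "evaluate")


@dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    n_scenes: int = 16
    image_size: int = 64
    n_grass: int = 1
    n_broadleaf: int = 1
    backbone: str = "tiny"
    test_fraction: float = 0.1  # train/test split honoured as a ratio
    train: TrainConfig = field(default_factory=lambda: TrainConfig(iterations=500))
    recode: RecodeParams = field(default_factory=RecodeParams)
    alpha: float = 1.0 / 3.0
    beta: float = 1.0 / 3.0
    match_iou: float = 0.5
    iog_score_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.n_scenes < 2:
            raise ValueError("n_scenes must be at least 2 (train + test)")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        EnsembleWeights(self.alpha, self.beta)  # validates the simplex constraint
        BackboneConfig(variant=self.backbone)  # validates the variant name

    def scene_seed(self, index: int) -> int:
        return (self.seed * 9973 + index) % (2**31 - 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        train_cfg = TrainConfig(**raw.pop("train", {}))
        recode_cfg = RecodeParams(**raw.pop("recode", {}))
        return cls(train=train_cfg, recode=recode_cfg, **raw)


def _log(stage: str, message: str) -> None:
    import sys

    print(f"[{time.strftime('%H:%M:%S')}] {stage}: {message}", file=sys.stderr)


class _Stage:
    """Skip-if-done wrapper so the pipeline is resumable per stage."""

    def __init__(self, name: str, done_marker: Path, resume: bool):
        self.name = name
        self.done_marker = done_marker
        self.resume = resume

    @property
    def skip(self) -> bool:
        return self.resume and self.done_marker.exists()


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute the full pipeline; returns the evaluation report as a dict.

    Stage failures raise with the failing stage named; outputs of completed
    stages are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))

    stage_dirs = {
        "scenes": out / "scenes",
        "pha": out / "pha",
        "detect": out / "detections",
    }
    weights_path = out / "weights.npz"
    report_path = out / "report.json"
    n = config.n_scenes
    n_test = max(1, round(n * config.test_fraction))
    train_ids = [f"{i:04d}" for i in range(n - n_test)]
    test_ids = [f"{i:04d}" for i in range(n - n_test, n)]

    try:
        # ---- generate ----------------------------------------------------
        stage = "generate"
        sdir = stage_dirs["scenes"]
        if not (resume and (sdir / "rig.yaml").exists()):
            _log(stage, f"rendering {n} synthetic scene pairs")
            for sub in ("rgb", "depth", "ann"):
                (sdir / sub).mkdir(parents=True, exist_ok=True)
            rig = None
            for i in range(n):
                scfg = SceneConfig(
                    image_size=(config.image_size, config.image_size),
                    n_grass=config.n_grass,
                    n_broadleaf=config.n_broadleaf,
                    seed=config.scene_seed(i),
                )
                pair = generate_scene(scfg)
                name = f"{i:04d}"
                write_color_png(pair.rgb, sdir / "rgb" / f"{name}.png")
                write_depth_png(pair.depth, sdir / "depth" / f"{name}.png")
                write_voc_annotations(pair.annotations, sdir / "ann" / f"{name}.xml",
                                      image_filename=f"{name}.png")
                rig = pair.camera
            rig.save(sdir / "rig.yaml")
        else:
            _log(stage, "resumed (outputs exist)")

        # ---- recode ------------------------------------------------------
        stage = "recode"
        pdir = stage_dirs["pha"]
        if not (resume and pdir.exists() and len(list(pdir.glob("*.png"))) == n):
            _log(stage, "hole filling + PHA recoding")
            pdir.mkdir(parents=True, exist_ok=True)
            rig = CameraRig.load(sdir / "rig.yaml")
            for i in range(n):
                name = f"{i:04d}"
                depth = read_depth_png(sdir / "depth" / f"{name}.png")
                pha = recode_to_pha(fill_holes(depth), rig, config.recode)
                write_color_png(pha.quantized, pdir / f"{name}.png")
        else:
            _log(stage, "resumed (outputs exist)")

        # ---- train -------------------------------------------------------
        stage = "train"
        net_cfg = NetworkConfig(backbone=BackboneConfig(variant=config.backbone)).scaled_for(
            config.image_size
        )
        if not (resume and weights_path.exists()):
            _log(stage, f"training {config.backbone} backbone on {len(train_ids)} images")
            dataset = []
            for name in train_ids:
                rgb = read_color(sdir / "rgb" / f"{name}.png")
                pha = read_color(pdir / f"{name}.png")
                anns = read_voc_annotations(sdir / "ann" / f"{name}.xml")
                dataset.append((rgb, pha, anns))
            tc = config.train
            tc.seed = config.seed
            net, result = train(dataset, net_config=net_cfg, config=tc)
            save_checkpoint(net, weights_path, tc)
            (out / "loss_log.json").write_text(json.dumps(result.loss_log))
        else:
            _log(stage, "resumed (weights exist)")

        # ---- detect ------------------------------------------------------
        stage = "detect"
        ddir = stage_dirs["detect"]
        branch_files = {b: ddir / f"{b}.jsonl" for b in ("rgb", "pha", "corr")}
        if not (resume and all(f.exists() for f in branch_files.values())):
            _log(stage, f"running the three branches on {len(test_ids)} test images")
            ddir.mkdir(parents=True, exist_ok=True)
            net = load_checkpoint(weights_path, net_cfg)
            per_branch: dict[str, dict[str, DetectionSet]] = {b: {} for b in branch_files}
            for name in test_ids:
                rgb = read_color(sdir / "rgb" / f"{name}.png")
                pha = read_color(pdir / f"{name}.png")
                outs = net(rgb, pha)
                for b in branch_files:
                    per_branch[b][name] = outs[b]
            for b, f in branch_files.items():
                write_detections_jsonl(per_branch[b], f)
        else:
            _log(stage, "resumed (detections exist)")

        # ---- ensemble ----------------------------------------------------
        stage = "ensemble"
        ens_path = ddir / "ensemble.jsonl"
        if not (resume and ens_path.exists()):
            _log(stage, f"decision-level fusion at alpha={config.alpha:.2f}, beta={config.beta:.2f}")
            weights = EnsembleWeights(config.alpha, config.beta)
            branch_sets = {b: read_detections_jsonl(f) for b, f in branch_files.items()}
            fused = {}
            for name in test_ids:
                fused[name] = fuse_detections(
                    branch_sets["rgb"].get(name, DetectionSet(source="rgb")),
                    branch_sets["pha"].get(name, DetectionSet(source="pha")),
                    branch_sets["corr"].get(name, DetectionSet(source="corr")),
                    weights,
                )
            write_detections_jsonl(fused, ens_path)
        else:
            _log(stage, "resumed (ensemble exists)")

        # ---- evaluate ----------------------------------------------------
        stage = "evaluate"
        _log(stage, "scoring mAP and IoG on the test split")
        dets = read_detections_jsonl(ens_path)
        anns = {name: read_voc_annotations(sdir / "ann" / f"{name}.xml") for name in test_ids}
        for name in test_ids:
            dets.setdefault(name, DetectionSet(source="ensemble"))
        report = evaluate(
            dets,
            anns,
            iou_threshold=config.match_iou,
            iog_score_threshold=config.iog_score_threshold,
        )
        payload = {
            "per_class_ap": report.per_class_ap,
            "map": report.map,
            "iog": report.iog,
            "iou_threshold": report.iou_threshold,
            "iog_score_threshold": report.iog_score_threshold,
            "n_train": len(train_ids),
            "n_test": len(test_ids),
        }
        report_path.write_text(json.dumps(payload, indent=2))
        _log(stage, f"mAP={report.map:.1f}% IoG={report.iog:.1f}% -> {report_path}")
        return payload
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
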