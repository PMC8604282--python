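"""Scored, class-labelled detection boxes and their JSONL interchange format."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rgbd_io import CLASS_NAMES

__all__ = ["DetectionSet", "write_detections_jsonl", "read_detections_jsonl"]

_BRANCHES = ("rgb", "pha", "corr", "ensemble")


@dataclass
class DetectionSet:
    """Detections from one branch (or the ensemble) for one image.

    Stored as parallel arrays; ``sort()`` enforces the descending-score
    order within each class that downstream matching assumes.
    """

    boxes: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))
    scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    labels: list[str] = field(default_factory=list)
    source: str = "rgb"

    def __post_init__(self) -> None:
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        self.labels = list(self.labels)
        if not (len(self.labels) == len(self.scores) == self.boxes.shape[0]):
            raise ValueError("boxes, scores and labels must have equal length")
        if self.source not in _BRANCHES:
            raise ValueError(f"source must be one of {_BRANCHES}")
        for lab in self.labels:
            if lab not in CLASS_NAMES:
                raise ValueError(f"unknown class {lab!r}")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    def sort(self) -> "DetectionSet":
        """Return a copy sorted by descending score (stable)."""
        order = np.argsort(-self.scores, kind="stable")
        return DetectionSet(
            self.boxes[order], self.scores[order], [self.labels[i] for i in order], self.source
        )

    def for_class(self, class_name: str) -> "DetectionSet":
        idx = [i for i, lab in enumerate(self.labels) if lab == class_name]
        return DetectionSet(
            self.boxes[idx], self.scores[idx], [self.labels[i] for i in idx], self.source
        )

    def filter_scores(self, threshold: float) -> "DetectionSet":
        idx = [i for i, s in enumerate(self.scores) if s >= threshold]
        return DetectionSet(
            self.boxes[idx], self.scores[idx], [self.labels[i] for i in idx], self.source
        )


def write_detections_jsonl(dets: dict[str, DetectionSet], path: str | Path) -> None:
    """Write per-image detection sets as JSON lines.

    Each line: ``{image_id, class, x1, y1, x2, y2, score, branch}``.
    """
    with open(path, "w") as fh:
        for image_id, ds in dets.items():
            for box, score, label in zip(ds.boxes, ds.scores, ds.labels):
                fh.write(
                    json.dumps(
                        {
                            "image_id": image_id,
                            "class": label,
                            "x1": float(box[0]),
                            "y1": float(box[1]),
                            "x2": float(box[2]),
                            "y2": float(box[3]),
                            "score": float(score),
                            "branch": ds.source,
                        }
                    )
                    + "\n"
                )


def read_detections_jsonl(path: str | Path) -> dict[str, DetectionSet]:
    """Read JSONL detections back into per-image :class:`DetectionSet` objects."""
    records: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise IOError(f"{path}:{lineno}: malformed JSON line") from exc
            img = records.setdefault(
                rec["image_id"], {"boxes": [], "scores": [], "labels": [], "branch": rec["branch"]}
            )
            img["boxes"].append([rec["x1"], rec["y1"], rec["x2"], rec["y2"]])
            img["scores"].append(rec["score"])
            img["labels"].append(rec["class"])
    return {
        image_id: DetectionSet(
            np.array(d["boxes"]).reshape(-1, 4), d["scores"], d["labels"], d["branch"]
        ).sort()
        for image_id, d in records.items()
    }
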