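"""Run the whole pipeline on disk: generate -> recode -> train -> detect ->
ensemble -> evaluate.

Writes PNG/XML/JSONL/JSON artifacts under ./scratch/pipeline_demo and prints
the held-out evaluation report.  Equivalent CLI:

    weedspot run --out scratch/pipeline_demo --n 12 --size 64 \
        --iterations 300 --seed 11
"""

from weedspot.pipeline import RunConfig, run_pipeline
from weedspot.training import TrainConfig

config = RunConfig(
    out_dir="scratch/pipeline_demo",
    seed=11,
    n_scenes=12,
    image_size=64,
    train=TrainConfig(iterations=300, seed=11),
)
report = run_pipeline(config)
print()
print(f"held-out images: {report['n_test']} (trained on {report['n_train']})")
print(f"per-class AP: {report['per_class_ap']}")
print(f"mAP: {report['map']:.1f}%  IoG: {report['iog']:.1f}%")
print("-> every stage left its artifacts under scratch/pipeline_demo;"
      " rerunning with resume=True reuses them.")
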