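"""Decision-level ensembling and the (alpha, beta) weight grid search.

Fuses three hand-built branch outputs with the weighted combination
G = alpha*g_rgb + beta*g_pha + (1-alpha-beta)*g_corr, then grid-searches
the weight simplex against a small validation set.
"""

import numpy as np

from weedspot.detections import DetectionSet
from weedspot.ensemble import EnsembleWeights, fuse_detections, grid_search_weights
from weedspot.rgbd_io import Annotation, AnnotationSet

# one weed, seen by all three branches with different confidence
box = np.array([[20, 20, 40, 40.0]])
rgb = DetectionSet(box, [0.9], ["grass"], "rgb")
pha = DetectionSet(box, [0.6], ["grass"], "pha")
corr = DetectionSet(box, [0.3], ["grass"], "corr")

weights = EnsembleWeights(alpha=0.4, beta=0.3)
fused = fuse_detections(rgb, pha, corr, weights)
print(f"branch scores (0.9, 0.6, 0.3) at weights (0.4, 0.3, 0.3) "
      f"-> fused score {fused.scores[0]:.2f}")
assert abs(fused.scores[0] - (0.4 * 0.9 + 0.3 * 0.6 + 0.3 * 0.3)) < 1e-12

# grid search: rgb is the only branch that localises this validation image
ann = AnnotationSet((64, 64), [Annotation("grass", (20, 20, 40, 40))])
outputs = {
    "img": {
        "rgb": DetectionSet(box, [1.0], ["grass"], "rgb"),
        "pha": DetectionSet(np.array([[23, 23, 43, 43.0]]), [1.0], ["grass"], "pha"),
        "corr": DetectionSet(np.array([[23, 23, 43, 43.0]]), [1.0], ["grass"], "corr"),
    }
}
best, surface = grid_search_weights(outputs, {"img": ann}, step=0.05, metric="iog")
print(f"grid: {len(surface)} feasible (alpha, beta) points at step 0.05")
best25, _ = grid_search_weights(outputs, {"img": ann}, step=0.25, metric="iog")
print(f"argmax at quarter steps: alpha={best25.alpha:.2f}, beta={best25.beta:.2f}")
print("-> with misaligned boxes in the other branches, coverage is maximised"
      " by trusting the accurate branch alone.")
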