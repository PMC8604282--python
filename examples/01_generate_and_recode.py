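"""Generate one synthetic wheat-field RGB-D scene and recode depth to PHA.

Builds a 128x128 top-down scene (tilted ground plane, wheat canopy, one
grass and one broad-leaf weed), repairs the depth holes, recodes depth into
the three-channel PHA image, and prints the recovered gravity direction and
the entropy comparison that motivates the recoding.
"""

import numpy as np

import weedspot as ws

config = ws.SceneConfig(image_size=(128, 128), n_grass=1, n_broadleaf=1, seed=7)
pair = ws.generate_scene(config)
print(f"scene: {pair.rgb.shape[1]}x{pair.rgb.shape[0]} px, "
      f"{len(pair.annotations.objects)} weeds "
      f"({', '.join(a.class_name for a in pair.annotations.objects)})")
print(f"depth holes: {(~pair.depth.valid_mask).sum()} px "
      f"({100 * (~pair.depth.valid_mask).mean():.1f}%)")

filled = ws.fill_holes(pair.depth)
pha = ws.recode_to_pha(filled, pair.camera)

est = pha.gravity
err = np.degrees(np.arccos(np.clip(abs(est.g @ pair.true_gravity), -1, 1)))
print(f"gravity estimated in {est.iterations} iterations from "
      f"{est.n_parallel} parallel + {est.n_perpendicular} perpendicular normals; "
      f"angular error vs ground truth: {err:.2f} deg")

e_pha = ws.image_entropy(pha.quantized)
e_depth = ws.image_entropy(ws.render_depth_8bit(filled, pha.d_max))
print(f"entropy: PHA {e_pha:.2f} bits vs raw depth {e_depth:.2f} bits")
print("-> the recoded image carries more usable structure per pixel than the"
      " monotone distance map, which is why the detector consumes PHA.")
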