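"""Align a depth raster into the color camera's pixel grid.

Uses a two-sensor rig with a 50 mm baseline along x and shows that a flat
surface at 700 mm shifts by the analytic disparity fx * tx / z while the
metric depth values are preserved exactly.
"""

import numpy as np

from weedspot.camera import CameraRig, intrinsics_matrix
from weedspot.rgbd_io import DepthRaster, align_depth_to_color

fx, z, tx = 120.0, 700.0, 50.0
K = intrinsics_matrix(fx, fx, 63.5, 63.5)
rig = CameraRig(K_depth=K, K_color=K.copy(), t=np.array([tx, 0.0, 0.0]))

depth = DepthRaster(np.full((128, 128), z))
aligned = align_depth_to_color(depth, rig, (128, 128))

shift = fx * tx / z
valid_cols = np.nonzero(aligned.valid_mask.any(axis=0))[0]
print(f"analytic disparity: fx*tx/z = {shift:.3f} px")
print(f"valid output columns start at {valid_cols.min()} "
      f"(expected ~{np.ceil(shift - 0.5):.0f} after the shift)")
print(f"depth values preserved: all aligned pixels = {np.unique(aligned.values[aligned.valid_mask])} mm")
print("-> alignment only moves samples (nearest-pixel splat with a z-buffer);"
      " it never interpolates new distances.")
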