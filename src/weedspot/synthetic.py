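"""Seedable generator of paired RGB + depth wheat-field scenes.

The generator emulates the statistical structure of a top-down RGB-D survey
of a weedy wheat field so that every downstream stage (alignment, recoding,
detection, ensembling, evaluation) can be exercised offline with known
ground truth:

* a ground plane perpendicular to gravity, ``camera_height`` mm below the
  camera, with the camera tilted away from nadir by up to ``tilt_max_deg``
  so gravity and the optical axis genuinely differ;
* a wheat canopy drawn from one green-hue texture family, standing
  ``wheat_height_range`` mm above ground;
* grass weeds rendered as thin elongated strokes whose colors are sampled
  from the *same* green family as wheat (ambiguous in RGB) but which stand
  taller than the canopy (distinct in depth);
* broad-leaf weeds rendered as compact lobed rosettes with a distinct
  blue-green color (distinct in both modalities);
* sensor artefacts: Gaussian depth noise and invalid ("hole") pixels placed
  preferentially at depth discontinuities, mimicking shielding losses.

Depth is exact pinhole geometry: a surface point at height ``h`` above the
ground along gravity ``g`` seen through pixel ray ``r = K^-1 (u, v, 1)`` has
z-depth ``d = (camera_height - h) / (g . r)``, so ground pixels lie exactly
on the tilted plane and plane normals recover gravity exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import CameraRig
from .rgbd_io import (
    Annotation,
    AnnotationSet,
    DepthRaster,
    write_voc_annotations as _write_voc,
)

__all__ = ["SceneConfig", "ScenePair", "generate_scene", "augment_pair", "write_voc_annotations"]


@dataclass
class SceneConfig:
    """Parameters of one synthetic wheat-field scene.

    Heights are in millimetres above ground; ``camera_height`` is the
    distance from the camera to the ground plane along gravity (the survey
    rig held the sensor about 700 mm above the canopy, hence the default).
    """

    image_size: tuple[int, int] = (500, 500)  # (H, W)
    camera_height: float = 700.0
    wheat_height_range: tuple[float, float] = (80.0, 200.0)
    grass_weed_height_range: tuple[float, float] = (250.0, 400.0)
    broadleaf_height_range: tuple[float, float] = (120.0, 280.0)
    n_grass: int = 3
    n_broadleaf: int = 2
    depth_noise_sd: float = 2.0
    hole_fraction: float = 0.05
    tilt_max_deg: float = 5.0
    max_box_overlap: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size must be positive")
        for name in ("wheat_height_range", "grass_weed_height_range", "broadleaf_height_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi")
            if hi >= self.camera_height:
                raise ValueError(f"{name} must stay below camera_height")
        if not 0.0 <= self.hole_fraction <= 1.0:
            raise ValueError("hole_fraction must lie in [0, 1]")
        if self.n_grass < 0 or self.n_broadleaf < 0:
            raise ValueError("weed counts must be non-negative")
        if self.depth_noise_sd < 0:
            raise ValueError("depth_noise_sd must be non-negative")


@dataclass
class ScenePair:
    """One generated scene: rasters, annotations, and generator ground truth.

    ``depth_clean`` (noise-free, hole-free depth), ``instance_masks`` and
    ``true_gravity`` are ground-truth fields only a synthetic scene can
    provide; they back parameter-recovery tests and are never serialised.
    """

    rgb: np.ndarray
    depth: DepthRaster
    annotations: AnnotationSet
    true_gravity: np.ndarray
    camera: CameraRig
    depth_clean: np.ndarray = None  # type: ignore[assignment]
    instance_masks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = np.asarray(self.true_gravity, dtype=float)
        if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-9):
            raise ValueError("true_gravity must be a unit vector")
        self.true_gravity = g


# ---------------------------------------------------------------------------
# painting helpers
# ---------------------------------------------------------------------------


def _smooth_noise(rng, shape, sigma):
    from scipy.ndimage import gaussian_filter

    n = rng.standard_normal(shape)
    n = gaussian_filter(n, sigma, mode="wrap")
    n -= n.min()
    rng_span = n.max() - n.min()
    return n / rng_span if rng_span > 0 else np.zeros(shape)


def _stroke_mask(shape, center, angle, length, halfwidth):
    """Boolean mask of a thick line segment (a grass-weed leaf bundle)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = np.cos(angle), np.sin(angle)
    rx = xx - center[0]
    ry = yy - center[1]
    t = rx * dx + ry * dy  # along-stroke coordinate
    s = -rx * dy + ry * dx  # across-stroke coordinate
    t_clamped = np.clip(t, -length / 2, length / 2)
    dist2 = (t - t_clamped) ** 2 + s**2
    return dist2 <= halfwidth**2


def _blob_mask(rng, shape, center, radius):
    """Compact lobed rosette: union of a few overlapping ellipses."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    n_lobes = int(rng.integers(3, 6))
    for _ in range(n_lobes):
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0.2, 0.5) * radius
        cx = center[0] + off * np.cos(ang)
        cy = center[1] + off * np.sin(ang)
        a = radius * rng.uniform(0.5, 0.8)
        b = radius * rng.uniform(0.35, 0.6)
        phi = rng.uniform(0, np.pi)
        rx = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
        ry = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
        mask |= (rx / a) ** 2 + (ry / b) ** 2 <= 1.0
    return mask


def _mask_box(mask):
    ys, xs = np.nonzero(mask)
    return (float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))


def _box_iou(a, b):
    x1 = max(a[0], b[0])
    y1 = max(a[1], b[1])
    x2 = min(a[2], b[2])
    y2 = min(a[3], b[3])
    inter = max(x2 - x1, 0) * max(y2 - y1, 0)
    area = lambda bb: (bb[2] - bb[0]) * (bb[3] - bb[1])  # noqa: E731
    union = area(a) + area(b) - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_scene(config: SceneConfig) -> ScenePair:
    """Render one RGB-D scene pair with VOC-style box annotations.

    Deterministic for a fixed ``config.seed`` (bit-identical rasters).
    Raises ``RuntimeError`` if the requested weed count cannot be placed
    without exceeding ``max_box_overlap`` between instance boxes.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size

    # camera: square pixels, ~53 deg FOV, principal point at the centre
    fx = float(w)
    rig = CameraRig.identity(fx, fx, (w - 1) / 2.0, (h - 1) / 2.0)

    # gravity: optical axis tilted away from nadir by <= tilt_max_deg
    tilt = np.deg2rad(rng.uniform(0.0, config.tilt_max_deg))
    azim = rng.uniform(0.0, 2 * np.pi)
    g = np.array([np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim), np.cos(tilt)])

    # per-pixel ray directions r = K^-1 (u, v, 1)
    vv, uu = np.mgrid[0:h, 0:w].astype(float)
    Kinv = np.linalg.inv(rig.K_depth)
    rays = np.stack([uu, vv, np.ones_like(uu)], axis=-1) @ Kinv.T
    g_dot_r = rays @ g  # > 0 for a near-nadir camera

    # --- height field -----------------------------------------------------
    height = np.zeros((h, w))
    scale = min(h, w)

    # wheat rows: stripes with wobble, plus patchy canopy texture
    row_period = scale * rng.uniform(0.12, 0.2)
    row_phase = rng.uniform(0, 2 * np.pi)
    wobble = _smooth_noise(rng, (h, w), scale * 0.04) * row_period * 0.35
    stripe = np.sin(2 * np.pi * (uu + wobble) / row_period + row_phase)
    canopy_noise = _smooth_noise(rng, (h, w), scale * 0.02)
    wheat_mask = (stripe > -0.2) & (canopy_noise > 0.25)
    wlo, whi = config.wheat_height_range
    wheat_h = wlo + (whi - wlo) * _smooth_noise(rng, (h, w), scale * 0.03)
    height[wheat_mask] = wheat_h[wheat_mask]

    # --- weeds ------------------------------------------------------------
    margin = int(0.12 * scale)
    specs = [("grass", config.n_grass), ("broadleaf", config.n_broadleaf)]
    placed_boxes: list[tuple[float, float, float, float]] = []
    annotations: list[Annotation] = []
    instance_masks: list[np.ndarray] = []
    weed_height = np.zeros((h, w))
    weed_kind = np.zeros((h, w), dtype=np.int8)  # 0 none, 1 grass, 2 broadleaf

    for class_name, count in specs:
        for _ in range(count):
            for attempt in range(60):
                cx = rng.uniform(margin, w - margin)
                cy = rng.uniform(margin, h - margin)
                if class_name == "grass":
                    mask = _stroke_mask(
                        (h, w),
                        (cx, cy),
                        rng.uniform(0, np.pi),
                        length=scale * rng.uniform(0.25, 0.4),
                        # floor ~5 px thickness so a box annotation stays
                        # meaningful at small raster sizes
                        halfwidth=max(2.5, scale * rng.uniform(0.015, 0.03)),
                    )
                    lo, hi = config.grass_weed_height_range
                else:
                    mask = _blob_mask(rng, (h, w), (cx, cy), radius=scale * rng.uniform(0.08, 0.13))
                    lo, hi = config.broadleaf_height_range
                if not mask.any():
                    continue
                box = _mask_box(mask)
                if any(_box_iou(box, b) > config.max_box_overlap for b in placed_boxes):
                    continue
                break
            else:
                raise RuntimeError(
                    f"could not place {class_name} weed #{len(placed_boxes) + 1} "
                    f"without exceeding max_box_overlap={config.max_box_overlap}"
                )
            placed_boxes.append(box)
            annotations.append(Annotation(class_name, box))
            instance_masks.append(mask)
            inst_h = rng.uniform(lo, hi) + 0.1 * (hi - lo) * (
                _smooth_noise(rng, (h, w), scale * 0.02) - 0.5
            )
            weed_height[mask] = np.maximum(weed_height[mask], inst_h[mask])
            weed_kind[mask] = 1 if class_name == "grass" else 2

    on_weed = weed_kind > 0
    height = np.where(on_weed, np.maximum(height, weed_height), height)

    # --- exact depth geometry ---------------------------------------------
    depth_clean = (config.camera_height - height) / g_dot_r

    depth_noisy = depth_clean + config.depth_noise_sd * rng.standard_normal((h, w))
    depth_noisy = np.clip(depth_noisy, 1.0, None)

    # holes preferentially at depth discontinuities (shielding)
    gy, gx = np.gradient(depth_clean)
    edge = np.hypot(gx, gy)
    edge = edge / (edge.mean() + 1e-12)
    weights = 1.0 + 3.0 * np.minimum(edge, 3.0)
    p = config.hole_fraction * weights / weights.mean()
    p = np.clip(p, 0.0, 1.0)
    holes = rng.random((h, w)) < p
    values = np.where(holes, 0.0, np.round(depth_noisy))
    depth = DepthRaster(values)

    # --- RGB --------------------------------------------------------------
    rgb = np.zeros((h, w, 3))
    soil = np.array([128.0, 96.0, 64.0]) + 18.0 * rng.standard_normal((h, w, 3))
    rgb[:] = soil

    def green_family(n_px, rng):
        """Shared wheat/grass-weed color distribution (RGB-ambiguous)."""
        r = rng.uniform(60, 110, n_px)
        gch = rng.uniform(110, 180, n_px)
        b = rng.uniform(30, 75, n_px)
        return np.stack([r, gch, b], axis=1)

    wm = wheat_mask & ~on_weed
    rgb[wm] = green_family(int(wm.sum()), rng)
    gm = weed_kind == 1
    rgb[gm] = green_family(int(gm.sum()), rng)
    bm = weed_kind == 2
    n_b = int(bm.sum())
    rgb[bm] = np.stack(
        [rng.uniform(25, 55, n_b), rng.uniform(105, 160, n_b), rng.uniform(80, 125, n_b)],
        axis=1,
    )

    # simple height shading + sensor noise
    shade = 0.75 + 0.25 * (height / max(height.max(), 1.0))
    rgb *= shade[..., None]
    rgb += 6.0 * rng.standard_normal((h, w, 3))
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    return ScenePair(
        rgb=rgb,
        depth=depth,
        annotations=AnnotationSet(image_size=(h, w), objects=annotations),
        true_gravity=g,
        camera=rig,
        depth_clean=depth_clean,
        instance_masks=instance_masks,
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_TRANSFORMS = ("rotate90k", "flip_h", "flip_v")


def _transform_box(box, transform, k, size):
    h, w = size
    x1, y1, x2, y2 = box
    if transform == "flip_h":
        return (w - x2, y1, w - x1, y2)
    if transform == "flip_v":
        return (x1, h - y2, x2, h - y1)
    # one CCW quarter-turn: (x, y) -> (y, W - x); iterate k times
    for _ in range(k % 4):
        x1, y1, x2, y2 = y1, w - x2, y2, w - x1
        h, w = w, h
    return (x1, y1, x2, y2)


def augment_pair(pair: ScenePair, transform: str, k: int = 1) -> ScenePair:
    """Apply a rigid raster symmetry consistently to rasters and boxes.

    ``transform`` is one of ``rotate90k`` (``k`` CCW quarter-turns),
    ``flip_h`` (left-right) or ``flip_v`` (top-bottom).  The transforms are
    about the optical axis, so ``true_gravity`` is unchanged only in the
    sense that it remains the recorded scene property; rasters, masks and
    boxes all move together.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {_TRANSFORMS}")

    if transform == "flip_h":
        op = lambda a: np.ascontiguousarray(np.flip(a, axis=1))  # noqa: E731
    elif transform == "flip_v":
        op = lambda a: np.ascontiguousarray(np.flip(a, axis=0))  # noqa: E731
    else:
        op = lambda a: np.ascontiguousarray(np.rot90(a, k, axes=(0, 1)))  # noqa: E731

    size = pair.annotations.image_size
    new_size = size if transform != "rotate90k" or k % 2 == 0 else (size[1], size[0])
    new_objects = [
        Annotation(a.class_name, _transform_box(a.box, transform, k, size))
        for a in pair.annotations.objects
    ]
    return ScenePair(
        rgb=op(pair.rgb),
        depth=DepthRaster(op(pair.depth.values), op(pair.depth.valid_mask)),
        annotations=AnnotationSet(image_size=new_size, objects=new_objects),
        true_gravity=pair.true_gravity.copy(),
        camera=pair.camera,
        depth_clean=None if pair.depth_clean is None else op(pair.depth_clean),
        instance_masks=[op(m) for m in pair.instance_masks],
    )


def write_voc_annotations(pair: ScenePair, path: str | Path, image_filename: str = "image.png") -> None:
    """Write the pair's annotations as one Pascal VOC XML file."""
    _write_voc(pair.annotations, path, image_filename=image_filename)
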