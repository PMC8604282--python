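"""Recode a depth raster into a three-channel PHA image.

A raw depth image stores one distance per pixel — poor input for a CNN that
expects the three correlated, texture-rich channels of an RGB image.  The
PHA recoding replaces distance with three geometric quantities:

* **P**hase: the depth folded into the sensor's uniqueness range
  ``2*pi*l`` millimetres, ``phi = (d mod 2*pi*l) / l`` in ``[0, 2*pi)``.
  Structured-light and active-stereo sensors measure depth through a
  periodic code; re-introducing the wrap restores high-frequency structure
  that a monotone distance map lacks.
* **H**eight above ground: ``H = d_max - d`` with ``d_max`` the maximum
  distance in the image (per-image by default), so the ground is 0 and
  plants are positive.
* **A**ngle with gravity: the angle between the local surface normal and
  the gravity direction, with gravity estimated from the normals themselves
  (ground normals align with gravity, standing leaves are perpendicular).

The three channels are quantised to 8-bit with fixed linear maps
(``P * 255 / 2pi``, ``H * 255 / d_max``, ``A * 255 / 180``) so the result is
structurally interchangeable with an RGB image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .camera import CameraRig
from .rgbd_io import DepthRaster

__all__ = [
    "RecodeParams",
    "GravityEstimate",
    "PHAImage",
    "compute_phase",
    "compute_height",
    "estimate_normals",
    "estimate_gravity",
    "compute_gravity_angle",
    "recode_to_pha",
    "render_depth_8bit",
    "image_entropy",
]


@dataclass
class RecodeParams:
    """Tunable parameters of the recoding.

    ``l`` sets the phase uniqueness range ``2*pi*l`` mm.  The sensor's true
    value is not public, so the default ``l = 64`` gives a ~402 mm range —
    at least two wraps over a 700 mm working distance plus canopy, enough to
    expose structure in the phase channel.
    """

    l: int = 64
    d_max: float | None = None  # None -> per-image maximum
    normal_window: int = 5
    gravity_angle_threshold: float = 20.0  # degrees
    max_gravity_iters: int = 20
    gravity_objective: str = "consistent"  # or "printed"

    def __post_init__(self) -> None:
        if int(self.l) != self.l or self.l < 1:
            raise ValueError("l must be a positive integer")
        self.l = int(self.l)
        if self.normal_window < 3 or self.normal_window % 2 == 0:
            raise ValueError("normal_window must be odd and >= 3")
        if self.gravity_objective not in ("consistent", "printed"):
            raise ValueError("gravity_objective must be 'consistent' or 'printed'")


@dataclass
class GravityEstimate:
    """Gravity direction recovered from a field of surface normals."""

    g: np.ndarray
    n_parallel: int
    n_perpendicular: int
    iterations: int
    objective: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float).reshape(3)
        if not np.isclose(np.linalg.norm(self.g), 1.0, atol=1e-6):
            raise ValueError("g must be unit-norm")


@dataclass
class PHAImage:
    """The recoded three-channel image plus its float channels."""

    phase: np.ndarray  # radians in [0, 2*pi)
    height: np.ndarray  # mm in [0, d_max]
    angle: np.ndarray  # degrees in [0, 180]
    quantized: np.ndarray  # uint8, (H, W, 3), channel order (P, H, A)
    gravity: GravityEstimate
    d_max: float


def _require_hole_free(depth: DepthRaster) -> None:
    if not depth.valid_mask.all():
        raise ValueError("depth raster must be hole-free; run fill_holes first")


def compute_phase(depth: DepthRaster, params: RecodeParams) -> np.ndarray:
    """Phase channel: ``phi = (d mod 2*pi*l) / l``, radians in ``[0, 2*pi)``.

    Periodic in depth with period ``2*pi*l`` mm; a depth exactly at a wrap
    boundary maps to 0 (half-open interval convention).
    """
    _require_hole_free(depth)
    period = 2.0 * np.pi * params.l
    return np.mod(depth.values, period) / params.l


def compute_height(depth: DepthRaster, d_max: float) -> np.ndarray:
    """Height-above-ground channel ``H = d_max - d``, mm in ``[0, d_max]``."""
    _require_hole_free(depth)
    observed = float(depth.values.max())
    if d_max < observed:
        raise ValueError(f"d_max={d_max} is below the observed maximum depth {observed}")
    return d_max - depth.values


def estimate_normals(depth: DepthRaster, rig: CameraRig, window: int = 5) -> np.ndarray:
    """Per-pixel unit surface normals from local least-squares plane fits.

    Each pixel's ``window x window`` neighbourhood is deprojected to 3-D and
    a plane is fitted by total least squares (smallest eigenvector of the
    local point covariance).  Normals are oriented toward the camera
    (``n_z <= 0`` for a camera looking along +z).  Rank-deficient
    neighbourhoods inherit the nearest well-conditioned estimate.
    """
    _require_hole_free(depth)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    h, w = depth.shape
    vv, uu = np.mgrid[0:h, 0:w].astype(float)
    Kinv = np.linalg.inv(rig.K_depth)
    rays = np.stack([uu, vv, np.ones_like(uu)], axis=-1) @ Kinv.T
    pts = rays * depth.values[..., None]  # (h, w, 3)

    size = (window, window)

    def box_mean(a):
        return ndimage.uniform_filter(a, size=size, mode="nearest")

    means = np.stack([box_mean(pts[..., i]) for i in range(3)], axis=-1)
    cov = np.empty((h, w, 3, 3))
    for i in range(3):
        for j in range(i, 3):
            m = box_mean(pts[..., i] * pts[..., j]) - means[..., i] * means[..., j]
            cov[..., i, j] = m
            cov[..., j, i] = m

    evals, evecs = np.linalg.eigh(cov.reshape(-1, 3, 3))
    normals = evecs[:, :, 0].reshape(h, w, 3)  # smallest-eigenvalue direction

    # orient toward the camera
    flip = normals[..., 2] > 0
    normals[flip] *= -1.0

    # well-conditioned: the plane residual (smallest eigenvalue) clearly
    # separated from the in-plane spread
    ev = evals.reshape(h, w, 3)
    good = ev[..., 1] > 10.0 * np.finfo(float).eps * np.maximum(ev[..., 2], 1.0)
    if not good.all():
        if not good.any():
            raise ValueError("no well-conditioned neighborhood for normal estimation")
        _, (iy, ix) = ndimage.distance_transform_edt(~good, return_indices=True)
        normals = normals[iy, ix]

    norms = np.linalg.norm(normals, axis=-1, keepdims=True)
    return normals / np.maximum(norms, 1e-12)


def estimate_gravity(normals: np.ndarray, params: RecodeParams | None = None) -> GravityEstimate:
    """Estimate the gravity direction from a field of surface normals.

    Starting from the camera's down axis (+z, optical axis of a near-nadir
    rig), each iteration classifies normals into a parallel set (within the
    angle threshold of ``g`` or ``-g``; dominated by ground pixels) and a
    perpendicular set (within the threshold of the plane orthogonal to
    ``g``; standing stems and leaf edges), then re-estimates ``g`` as an
    extremal eigenvector of the scatter-difference matrix
    ``M = sum_{parallel} n n^T - sum_{perp} n n^T``.

    With the default ``consistent`` objective the parallel set pulls ``g``
    toward itself and the perpendicular set pushes it orthogonal
    (``min sum_par sin^2 + sum_perp cos^2`` = largest eigenvector of ``M``);
    the ``printed`` switch selects the transposed form
    (``min sum_par cos^2 + sum_perp sin^2``, smallest eigenvector).
    Iteration stops when ``g`` moves by less than 0.1 degrees.
    """
    params = params or RecodeParams()
    n = np.asarray(normals, dtype=float).reshape(-1, 3)
    if n.shape[0] == 0:
        raise ValueError("no normals supplied")
    n = n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-12)

    down = np.array([0.0, 0.0, 1.0])
    g = down.copy()
    cos_thr = np.cos(np.deg2rad(params.gravity_angle_threshold))
    sin_thr = np.sin(np.deg2rad(params.gravity_angle_threshold))

    n_par = n_perp = 0
    iters = 0
    converged = False
    for iters in range(1, params.max_gravity_iters + 1):
        c = np.abs(n @ g)
        par = c > cos_thr
        perp = c < sin_thr
        n_par, n_perp = int(par.sum()), int(perp.sum())
        if n_par + n_perp == 0:
            raise ValueError("no normals classified; increase gravity_angle_threshold")
        M = n[par].T @ n[par] - n[perp].T @ n[perp]
        evals, evecs = np.linalg.eigh(M)
        idx = -1 if params.gravity_objective == "consistent" else 0
        g_new = evecs[:, idx]
        if g_new @ down < 0:
            g_new = -g_new
        delta = np.degrees(np.arccos(np.clip(abs(g_new @ g), -1.0, 1.0)))
        g = g_new
        if delta < 0.1:
            converged = True
            break

    c = np.abs(n @ g)
    par = c > cos_thr
    perp = c < sin_thr
    cos2 = (n[par] @ g) ** 2
    sin2 = 1.0 - (n[perp] @ g) ** 2
    if params.gravity_objective == "consistent":
        objective = float(np.sum(1.0 - cos2) + np.sum(1.0 - sin2))
    else:
        objective = float(np.sum(cos2) + np.sum(sin2))
    return GravityEstimate(
        g=g,
        n_parallel=int(par.sum()),
        n_perpendicular=int(perp.sum()),
        iterations=iters,
        objective=objective,
        converged=converged,
    )


def compute_gravity_angle(normals: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Angle channel: ``theta = arccos(n . g)`` in degrees, ``[0, 180]``.

    Normals are camera-oriented and the angle is not folded to ``[0, 90]``,
    so up- and down-facing surfaces remain distinguishable.
    """
    g = np.asarray(g, dtype=float).reshape(3)
    if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-6):
        raise ValueError("g must be unit-norm")
    dots = np.clip(np.asarray(normals, dtype=float) @ g, -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def recode_to_pha(
    depth: DepthRaster, rig: CameraRig, params: RecodeParams | None = None
) -> PHAImage:
    """Assemble the full PHA image from a hole-free depth raster."""
    params = params or RecodeParams()
    _require_hole_free(depth)
    phase = compute_phase(depth, params)
    d_max = float(params.d_max) if params.d_max is not None else float(depth.values.max())
    height = compute_height(depth, d_max)
    normals = estimate_normals(depth, rig, params.normal_window)
    gravity = estimate_gravity(normals, params)
    angle = compute_gravity_angle(normals, gravity.g)

    q = np.stack(
        [
            phase * (255.0 / (2.0 * np.pi)),
            height * (255.0 / d_max) if d_max > 0 else np.zeros_like(height),
            angle * (255.0 / 180.0),
        ],
        axis=-1,
    )
    quantized = np.clip(np.round(q), 0, 255).astype(np.uint8)
    return PHAImage(
        phase=phase, height=height, angle=angle, quantized=quantized,
        gravity=gravity, d_max=d_max,
    )


def render_depth_8bit(depth: DepthRaster, d_max: float | None = None) -> np.ndarray:
    """Render raw depth as an 8-bit raster with the fixed map ``255 * d / d_max``.

    Uses the same linear-quantisation convention as the PHA channels so
    entropy comparisons between raw depth and its recoding are like-for-like.
    """
    d_max = float(d_max) if d_max is not None else float(depth.values.max())
    if d_max <= 0:
        return np.zeros(depth.shape, dtype=np.uint8)
    return np.clip(np.round(depth.values * (255.0 / d_max)), 0, 255).astype(np.uint8)


def image_entropy(raster: np.ndarray) -> float:
    """Shannon entropy (bits) of an 8-bit raster's 256-bin histogram.

    For a 3-channel raster the per-channel entropies are averaged.
    The result lies in ``[0, 8]`` bits.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty raster")
    if raster.dtype != np.uint8:
        raise ValueError("entropy is defined on 8-bit rasters")
    if raster.ndim == 2:
        raster = raster[..., None]
    if raster.ndim != 3 or raster.shape[2] not in (1, 3):
        raise ValueError("raster must have 1 or 3 channels")
    ents = []
    for c in range(raster.shape[2]):
        counts = np.bincount(raster[..., c].ravel(), minlength=256).astype(float)
        p = counts / counts.sum()
        nz = p[p > 0]
        ents.append(float(-(nz * np.log2(nz)).sum()))
    return float(np.mean(ents))
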