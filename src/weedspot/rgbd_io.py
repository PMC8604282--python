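"""Raster and annotation I/O, depth-to-color alignment, and hole filling.

Formats
-------
* depth: 16-bit single-channel PNG, millimetre units, 0 = invalid (the common
  sentinel for consumer depth sensors);
* color: 8-bit 3-channel PNG or JPEG;
* annotations: Pascal VOC XML (the format LabelImg emits), 1-based inclusive
  box coordinates on disk, converted to 0-based half-open rectangles in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image

from .camera import CameraRig

__all__ = [
    "DepthRaster",
    "Annotation",
    "AnnotationSet",
    "CLASS_NAMES",
    "read_depth_png",
    "write_depth_png",
    "read_color",
    "write_color_png",
    "read_voc_annotations",
    "write_voc_annotations",
    "align_depth_to_color",
    "fill_holes",
]

#: The fixed two-class vocabulary: grass weeds (shape-similar to wheat,
#: ambiguous in RGB) and broad-leaf weeds (morphologically distinct).
CLASS_NAMES = ("grass", "broadleaf")


@dataclass
class DepthRaster:
    """Single-channel distance image in millimetres with a validity mask.

    ``valid_mask`` is False exactly where ``values == 0`` (the invalid
    sentinel); all stored distances are non-negative.
    """

    values: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    units: str = "mm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("depth raster must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("depth values must be non-negative")
        if self.valid_mask is None:
            self.valid_mask = self.values > 0
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValueError("valid_mask shape mismatch")
            # enforce the sentinel contract
            self.values = np.where(self.valid_mask, self.values, 0.0)
            if np.any(self.values[self.valid_mask] == 0):
                raise ValueError("valid pixels must have positive depth")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "DepthRaster":
        return DepthRaster(self.values.copy(), self.valid_mask.copy(), self.units)


@dataclass
class Annotation:
    """One labelled object: class name and 0-based half-open pixel rectangle."""

    class_name: str
    box: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(
                f"unknown class {self.class_name!r}; expected one of {CLASS_NAMES}"
            )
        self.box = tuple(float(v) for v in self.box)


@dataclass
class AnnotationSet:
    """Annotations for one image plus the image size ``(H, W)``."""

    image_size: tuple[int, int]
    objects: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, w = self.image_size
        for ann in self.objects:
            x1, y1, x2, y2 = ann.box
            if not (0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h):
                raise ValueError(f"box {ann.box} outside image {self.image_size}")

    def boxes(self) -> np.ndarray:
        if not self.objects:
            return np.zeros((0, 4))
        return np.array([a.box for a in self.objects], dtype=float)

    def labels(self) -> list[str]:
        return [a.class_name for a in self.objects]


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------


def read_depth_png(path: str | Path) -> DepthRaster:
    """Read a 16-bit depth PNG (mm); zero pixels become invalid."""
    path = Path(path)
    try:
        img = Image.open(path)
        arr = np.array(img)
    except Exception as exc:  # noqa: BLE001 - report file context
        raise IOError(f"cannot read depth raster {path}: {exc}") from exc
    if arr.ndim != 2:
        raise IOError(f"{path}: depth PNG must be single-channel, got shape {arr.shape}")
    return DepthRaster(arr.astype(np.float64))


def write_depth_png(depth: DepthRaster, path: str | Path) -> None:
    """Write a depth raster as 16-bit PNG; invalid pixels are written as 0."""
    vals = np.where(depth.valid_mask, np.round(depth.values), 0.0)
    if np.any(vals > 65535):
        raise ValueError("depth exceeds the 16-bit range (65535 mm)")
    img = Image.fromarray(vals.astype(np.uint16))
    img.save(Path(path), format="PNG")


def read_color(path: str | Path) -> np.ndarray:
    """Read a color image as an 8-bit ``(H, W, 3)`` array."""
    path = Path(path)
    try:
        img = Image.open(path).convert("RGB")
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read color raster {path}: {exc}") from exc
    return np.array(img, dtype=np.uint8)


def write_color_png(rgb: np.ndarray, path: str | Path) -> None:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3 or rgb.dtype != np.uint8:
        raise ValueError("color raster must be 8-bit (H, W, 3)")
    Image.fromarray(rgb).save(Path(path), format="PNG")


# ---------------------------------------------------------------------------
# Pascal VOC XML
# ---------------------------------------------------------------------------


def write_voc_annotations(
    anns: AnnotationSet, path: str | Path, image_filename: str = "image.png"
) -> None:
    """Write one Pascal VOC XML file.

    Internal half-open 0-based boxes ``[x1, x2) x [y1, y2)`` are converted to
    VOC's 1-based inclusive convention: ``xmin = x1 + 1, xmax = x2``.
    """
    h, w = anns.image_size
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = image_filename
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(int(w))
    etree.SubElement(size, "height").text = str(int(h))
    etree.SubElement(size, "depth").text = "3"
    for ann in anns.objects:
        x1, y1, x2, y2 = ann.box
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = ann.class_name
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(x1)) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(round(y1)) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(round(x2)))
        etree.SubElement(bnd, "ymax").text = str(int(round(y2)))
    tree = etree.ElementTree(root)
    try:
        tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write VOC annotations to {path}: {exc}") from exc


def read_voc_annotations(path: str | Path) -> AnnotationSet:
    """Parse a Pascal VOC XML file into internal half-open 0-based boxes."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"malformed VOC XML {path}: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise IOError(f"{path}: missing <size> node")
    w = int(size.findtext("width"))
    h = int(size.findtext("height"))
    objects = []
    for i, obj in enumerate(root.findall("object")):
        name = obj.findtext("name")
        if name is None:
            raise IOError(f"{path}: <object> #{i} is missing its <name> node")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise IOError(f"{path}: <object> #{i} ({name}) is missing <bndbox>")
        try:
            xmin = float(bnd.findtext("xmin"))
            ymin = float(bnd.findtext("ymin"))
            xmax = float(bnd.findtext("xmax"))
            ymax = float(bnd.findtext("ymax"))
        except (TypeError, ValueError) as exc:
            raise IOError(f"{path}: <object> #{i} ({name}) has a malformed <bndbox>") from exc
        # VOC 1-based inclusive -> 0-based half-open
        objects.append(Annotation(name, (xmin - 1, ymin - 1, xmax, ymax)))
    return AnnotationSet(image_size=(h, w), objects=objects)


# ---------------------------------------------------------------------------
# depth-to-color alignment
# ---------------------------------------------------------------------------


def align_depth_to_color(
    depth: DepthRaster, rig: CameraRig, out_size: tuple[int, int]
) -> DepthRaster:
    """Resample a depth raster into the color camera's pixel grid.

    Each valid depth pixel is deprojected with the depth intrinsics,
    transformed by the rig extrinsics (R, t), reprojected with the color
    intrinsics, and splatted to its nearest output pixel.  When several depth
    pixels land on the same color pixel the nearest surface wins (z-buffer),
    which is what a physical camera would see.  Output pixels no depth pixel
    maps to are invalid — metric values are only moved, never interpolated.
    """
    if depth.values.size == 0:
        raise ValueError("empty depth raster")
    out_h, out_w = out_size
    out = np.zeros((out_h, out_w), dtype=np.float64)
    if not depth.valid_mask.any():
        return DepthRaster(out)
    v_idx, u_idx = np.nonzero(depth.valid_mask)
    d = depth.values[v_idx, u_idx]
    pts = rig.deproject_depth(u_idx.astype(float), v_idx.astype(float), d)
    pts_c = rig.depth_to_color_frame(pts)
    u, v, z = rig.project_color(pts_c)
    ui = np.round(u).astype(int)
    vi = np.round(v).astype(int)
    ok = (z > 0) & (ui >= 0) & (ui < out_w) & (vi >= 0) & (vi < out_h)
    ui, vi, z = ui[ok], vi[ok], z[ok]
    zbuf = np.full((out_h, out_w), np.inf)
    np.minimum.at(zbuf, (vi, ui), z)
    out = np.where(np.isfinite(zbuf), zbuf, 0.0)
    return DepthRaster(out)


# ---------------------------------------------------------------------------
# hole filling
# ---------------------------------------------------------------------------


def _median_of_valid_neighbors(values, valid, window):
    """Median over each pixel's valid neighbours in a window x window patch."""
    r = window // 2
    h, w = values.shape
    padded_v = np.pad(values, r, constant_values=np.nan)
    padded_m = np.pad(valid, r, constant_values=False)
    stack = np.empty((window * window, h, w))
    k = 0
    for dy in range(window):
        for dx in range(window):
            tile = padded_v[dy : dy + h, dx : dx + w]
            mask = padded_m[dy : dy + h, dx : dx + w]
            stack[k] = np.where(mask, tile, np.nan)
            k += 1
    with np.errstate(all="ignore"):
        return np.nanmedian(stack, axis=0)


def fill_holes(depth: DepthRaster, max_window: int = 101) -> DepthRaster:
    """Fill invalid pixels with the median of valid neighbours.

    Iterates with a growing window (3, 5, 7, ...) until no invalid pixels
    remain.  Originally valid pixels are never modified, filled values always
    lie within the range of the valid input values (a median cannot leave it),
    and the operation is idempotent: a hole-free raster passes through
    unchanged.
    """
    if not depth.valid_mask.any():
        raise ValueError("cannot fill a raster with no valid pixels")
    values = depth.values.copy()
    valid = depth.valid_mask.copy()
    window = 3
    while not valid.all():
        med = _median_of_valid_neighbors(values, valid, window)
        fillable = ~valid & np.isfinite(med)
        values[fillable] = med[fillable]
        valid |= fillable
        if not fillable.any():
            window += 2
            if window > max_window:
                raise RuntimeError("hole filling failed to converge")
    return DepthRaster(values, np.ones_like(valid))
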