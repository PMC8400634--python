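"""Domain types, coordinate conventions, annotation I/O and unit conversion.

Conventions used throughout the package:

* pixel coordinates are 0-based, ``x`` increases rightward, ``y`` increases
  downward (image convention); "deeper" therefore means larger ``y``;
* bounding boxes are axis-aligned and half-open, ``[min, max)``, when
  rasterised for area computations;
* boxes are stored in corner form (:class:`CornerBox`) everywhere except at
  the detection interface, which works with center/size boxes
  (:class:`CenterBox`);
* physical scale is a microns-per-pixel factor, either a single isotropic
  value or an ``(sx, sy)`` pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree
from PIL import Image

#: Class labels understood by the annotation readers/writers, in mask order:
#: background = 0, BMO = 1, LC = 2.
KNOWN_LABELS = ("BMO", "LC")

MASK_BACKGROUND = 0
MASK_BMO = 1
MASK_LC = 2


class DegenerateGeometryError(ValueError):
    """A box, line or curve has collapsed to zero extent."""


class AnnotationParseError(ValueError):
    """An annotation document is malformed or inconsistent."""


class BoundaryGapError(ValueError):
    """A boundary polyline has no support at the requested abscissa."""


def scale_xy(scale: float | tuple[float, float]) -> tuple[float, float]:
    """Normalise a microns-per-pixel scale to an ``(sx, sy)`` pair."""
    if np.isscalar(scale):
        s = float(scale)  # type: ignore[arg-type]
        if s <= 0:
            raise ValueError(f"scale must be positive, got {s}")
        return s, s
    sx, sy = (float(v) for v in scale)  # type: ignore[misc]
    if sx <= 0 or sy <= 0:
        raise ValueError(f"scale components must be positive, got {(sx, sy)}")
    return sx, sy


@dataclass(frozen=True)
class BScan:
    """A 2-D grayscale OCT B-scan with a physical pixel scale.

    Parameters
    ----------
    pixels
        2-D float array, intensities in [0, 1].
    microns_per_pixel
        Physical size of one pixel in μm, isotropic or ``(sx, sy)``.
    """

    pixels: np.ndarray
    microns_per_pixel: float | tuple[float, float] = 4.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError(f"image must be at least 64x64, got {px.shape}")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        scale_xy(self.microns_per_pixel)  # validates positivity
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CornerBox:
    """Axis-aligned box in (xmin, ymin, xmax, ymax) pixel corner form."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    label: str = "BMO"

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise DegenerateGeometryError(
                f"degenerate box: ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )
        if self.label not in KNOWN_LABELS:
            raise ValueError(f"unknown box label {self.label!r}; expected one of {KNOWN_LABELS}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def clipped(self, width: int, height: int) -> "CornerBox":
        """Clip to the image frame, preserving the label."""
        return CornerBox(
            max(0.0, self.xmin),
            max(0.0, self.ymin),
            min(float(width), self.xmax),
            min(float(height), self.ymax),
            self.label,
        )


@dataclass(frozen=True)
class CenterBox:
    """Axis-aligned box in (xc, yc, w, h) pixel center/size form."""

    xc: float
    yc: float
    w: float
    h: float
    label: str = "BMO"

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise DegenerateGeometryError(f"degenerate box size: ({self.w}, {self.h})")
        if self.label not in KNOWN_LABELS:
            raise ValueError(f"unknown box label {self.label!r}; expected one of {KNOWN_LABELS}")


def corners_to_center(box: CornerBox) -> CenterBox:
    """Convert a corner box to center/size form.

    ``xc = (xmin + xmax) / 2``, ``yc = (ymin + ymax) / 2``,
    ``w = xmax − xmin``, ``h = ymax − ymin``.
    """
    return CenterBox(
        xc=(box.xmin + box.xmax) / 2.0,
        yc=(box.ymin + box.ymax) / 2.0,
        w=box.xmax - box.xmin,
        h=box.ymax - box.ymin,
        label=box.label,
    )


def center_to_corners(box: CenterBox) -> CornerBox:
    """Exact algebraic inverse of :func:`corners_to_center`."""
    return CornerBox(
        xmin=box.xc - box.w / 2.0,
        ymin=box.yc - box.h / 2.0,
        xmax=box.xc + box.w / 2.0,
        ymax=box.yc + box.h / 2.0,
        label=box.label,
    )


@dataclass(frozen=True)
class BMOPair:
    """The two Bruch's membrane termination points of one B-scan."""

    left: tuple[float, float]
    right: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.left[0] < self.right[0]:
            raise ValueError(
                f"left BMO point must lie left of the right one: {self.left} vs {self.right}"
            )

    def inside(self, width: int, height: int) -> bool:
        return all(
            0 <= p[0] < width and 0 <= p[1] < height for p in (self.left, self.right)
        )


@dataclass
class AnnotatedScene:
    """One B-scan with its full ground-truth or predicted annotation."""

    image: BScan
    boxes: list[CornerBox]
    bmo: BMOPair
    lc_boundary: np.ndarray  # (N, 2) array of (x, y), x strictly increasing
    mask: np.ndarray  # int array, same shape as image, values in {0, 1, 2}

    def __post_init__(self) -> None:
        self.lc_boundary = np.asarray(self.lc_boundary, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.lc_boundary.ndim != 2 or self.lc_boundary.shape[1] != 2:
            raise ValueError("lc_boundary must be an (N, 2) array")
        if not np.all(np.diff(self.lc_boundary[:, 0]) > 0):
            raise ValueError("lc_boundary x-coordinates must be strictly increasing")
        if self.mask.shape != self.image.pixels.shape:
            raise ValueError("mask shape must match the image")
        if not np.isin(self.mask, (MASK_BACKGROUND, MASK_BMO, MASK_LC)).all():
            raise ValueError("mask classes must be in {0, 1, 2}")


@dataclass(frozen=True)
class Morphometry:
    """Quantified anterior-LC morphology of one B-scan.

    LCD (lamina cribrosa depth): maximum perpendicular distance from the
    BMO reference line to the anterior LC surface, μm. LCCD (LC curve
    depth): maximum depth from the LC width chord to the surface, μm.
    W: length of the width chord, μm. LCCI: ``LCCD / W × 100``,
    dimensionless.
    """

    lcd: float
    lccd: float
    width: float
    lcci: float
    geometry: dict | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if min(self.lcd, self.lccd, self.width) < 0:
            raise ValueError("LCD, LCCD and W must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {"LCD_um": self.lcd, "LCCD_um": self.lccd, "W_um": self.width, "LCCI": self.lcci}


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

def pixels_to_microns(length_px: float, scale: float) -> float:
    """Convert a pixel length to μm given a μm/px scale factor."""
    if length_px < 0:
        raise ValueError(f"length must be non-negative, got {length_px}")
    sx, sy = scale_xy(scale)
    if sx != sy:
        raise ValueError("pixels_to_microns needs an isotropic scale; scale x/y separately")
    return float(length_px) * sx


# ---------------------------------------------------------------------------
# Pascal-VOC (LabelImg dialect) bounding-box annotations
# ---------------------------------------------------------------------------

def write_annotations(
    boxes: Sequence[CornerBox],
    path: str | Path,
    image_size: tuple[int, int] | None = None,
    image_name: str = "scene.png",
) -> None:
    """Write boxes as a Pascal-VOC XML document (LabelImg dialect).

    ``image_size`` is ``(height, width)``; when given it is recorded in the
    ``<size>`` element and boxes are checked against it on read-back.
    """
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = image_name
    if image_size is not None:
        size = etree.SubElement(root, "size")
        etree.SubElement(size, "width").text = str(int(image_size[1]))
        etree.SubElement(size, "height").text = str(int(image_size[0]))
        etree.SubElement(size, "depth").text = "1"
    for box in boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = box.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = repr(float(box.xmin))
        etree.SubElement(bnd, "ymin").text = repr(float(box.ymin))
        etree.SubElement(bnd, "xmax").text = repr(float(box.xmax))
        etree.SubElement(bnd, "ymax").text = repr(float(box.ymax))
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


def _bnd_value(bnd: etree._Element, tag: str) -> float:
    el = bnd.find(tag)
    if el is None or el.text is None:
        raise AnnotationParseError(f"bndbox is missing a <{tag}> element")
    try:
        return float(el.text)
    except ValueError as exc:
        raise AnnotationParseError(f"<{tag}> is not a number: {el.text!r}") from exc


def read_annotations(path: str | Path) -> list[CornerBox]:
    """Read Pascal-VOC XML boxes written by LabelImg (or this package).

    Raises :class:`AnnotationParseError` naming the offending element for
    malformed documents, unknown class names and out-of-bounds boxes.
    """
    path = Path(path)
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise AnnotationParseError(f"malformed XML in {path}: {exc}") from exc
    if root.tag != "annotation":
        raise AnnotationParseError(f"root element is <{root.tag}>, expected <annotation>")

    size_el = root.find("size")
    frame = None
    if size_el is not None:
        try:
            frame = (int(size_el.findtext("width")), int(size_el.findtext("height")))
        except (TypeError, ValueError) as exc:
            raise AnnotationParseError("<size> element has non-integer dimensions") from exc

    boxes: list[CornerBox] = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if name is None:
            raise AnnotationParseError("<object> is missing a <name> element")
        if name not in KNOWN_LABELS:
            raise AnnotationParseError(f"unknown class name <name>{name}</name>")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationParseError(f"<object> {name!r} has no <bndbox>")
        xmin, ymin = _bnd_value(bnd, "xmin"), _bnd_value(bnd, "ymin")
        xmax, ymax = _bnd_value(bnd, "xmax"), _bnd_value(bnd, "ymax")
        try:
            box = CornerBox(xmin, ymin, xmax, ymax, label=name)
        except DegenerateGeometryError as exc:
            raise AnnotationParseError(f"degenerate <bndbox> for {name!r}: {exc}") from exc
        if frame is not None and (
            xmin < 0 or ymin < 0 or xmax > frame[0] or ymax > frame[1]
        ):
            raise AnnotationParseError(
                f"<bndbox> of {name!r} lies outside the {frame[0]}x{frame[1]} frame"
            )
        boxes.append(box)
    return boxes


# ---------------------------------------------------------------------------
# Image / mask / landmark I/O
# ---------------------------------------------------------------------------

_MASK_PALETTE = [0, 0, 0, 255, 64, 64, 64, 160, 255] + [0] * (256 * 3 - 9)


def save_bscan(image: BScan, path: str | Path) -> None:
    """Save a B-scan as an 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.round(image.pixels * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def load_bscan(path: str | Path, microns_per_pixel: float | tuple[float, float] = 4.0) -> BScan:
    """Load a grayscale PNG/TIFF as a B-scan with intensities in [0, 1]."""
    arr = np.asarray(Image.open(str(path)).convert("L"), dtype=float) / 255.0
    return BScan(arr, microns_per_pixel=microns_per_pixel)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Save a class mask as an 8-bit indexed PNG (0=background, 1=BMO, 2=LC)."""
    img = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="P")
    img.putpalette(_MASK_PALETTE)
    img.save(str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = Image.open(str(path))
    return np.asarray(img, dtype=np.int64)


def save_landmarks(bmo: BMOPair, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"left": list(bmo.left), "right": list(bmo.right)}, indent=2)
    )


def load_landmarks(path: str | Path) -> BMOPair:
    data = json.loads(Path(path).read_text())
    return BMOPair(left=tuple(data["left"]), right=tuple(data["right"]))


def save_morphometry(records: Iterable[Morphometry], path: str | Path) -> None:
    """Write morphometry records as a CSV with a fixed header."""
    lines = ["LCD_um,LCCD_um,W_um,LCCI"]
    for m in records:
        lines.append(f"{m.lcd:.2f},{m.lccd:.2f},{m.width:.2f},{m.lcci:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")
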