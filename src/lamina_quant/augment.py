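"""Training-time augmentation: vessel shadows, affine transforms, noise.

Vessel shadows emulate the dark full-height bands cast by overlying retinal
vessels: a band of width ``W''`` starting at a uniformly drawn column is
multiplied by ``1/S`` with the shadow factor ``S >= 1`` drawn uniformly
from a configured range, so shadows only ever darken. Geometric transforms
apply one sampled affine map consistently to the image, mask, boxes,
landmarks and boundary polyline. Noise is additive Gaussian or a
horizontal box-kernel motion blur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .core import (
    MASK_BMO,
    MASK_LC,
    AnnotatedScene,
    BMOPair,
    BScan,
    CornerBox,
)


class RejectedSampleError(RuntimeError):
    """No valid transform was found within the retry budget."""


@dataclass(frozen=True)
class ShadowConfig:
    """Vessel-shadow augmentation parameters.

    ``factor_range`` is the inclusive range of the shadow factor S (S >= 1;
    intensities in the band are multiplied by 1/S), ``shadow_width`` the
    band width W'' in px, ``count`` the number of bands per image.
    """

    factor_range: tuple[float, float] = (2.0, 8.0)
    shadow_width: int = 40
    count: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.factor_range
        if lo < 1.0 or hi < lo:
            raise ValueError(f"shadow factors must satisfy 1 <= lo <= hi, got {self.factor_range}")
        if self.shadow_width < 1:
            raise ValueError("shadow_width must be positive")
        if self.count < 0:
            raise ValueError("count must be non-negative")


def vessel_shadow(image: BScan, cfg: ShadowConfig, seed: int | None = None) -> BScan:
    """Darken ``cfg.count`` random full-height vertical bands by 1/S each.

    The band start column is drawn uniformly from ``[W'', width - W'']``
    and the band spans the full image height. Pixels outside the bands are
    untouched; no pixel intensity ever increases.
    """
    w = image.width
    if cfg.shadow_width >= w / 2:
        raise ValueError(f"shadow width {cfg.shadow_width} must be < half the image width {w}")
    rng = np.random.default_rng(seed)
    out = image.pixels.copy()
    for _ in range(cfg.count):
        start = int(rng.integers(cfg.shadow_width, w - cfg.shadow_width + 1))
        s = float(rng.uniform(*cfg.factor_range))
        out[:, start : start + cfg.shadow_width] *= 1.0 / s
    return BScan(np.clip(out, 0.0, 1.0), microns_per_pixel=image.microns_per_pixel)


@dataclass(frozen=True)
class GeometricParams:
    """Symmetric ranges for the random affine augmentation."""

    rotate_deg: float = 5.0
    shift_px: float = 20.0
    zoom: tuple[float, float] = (0.9, 1.1)
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.rotate_deg < 0 or self.shift_px < 0:
            raise ValueError("rotation and shift ranges must be non-negative")
        if not (0 < self.zoom[0] <= self.zoom[1]):
            raise ValueError("zoom range must be positive and ordered")


def _affine_about_center(
    shape: tuple[int, int], angle_deg: float, shift: tuple[float, float], zoom: float
) -> sktransform.AffineTransform:
    h, w = shape
    center = np.array([w / 2.0, h / 2.0])
    t_c = sktransform.AffineTransform(translation=-center)
    t_a = sktransform.AffineTransform(rotation=np.deg2rad(angle_deg), scale=zoom)
    t_b = sktransform.AffineTransform(translation=center + np.asarray(shift))
    return sktransform.AffineTransform(matrix=t_b.params @ t_a.params @ t_c.params)


def _tighten_box(box: CornerBox, mask: np.ndarray, cls: int) -> CornerBox:
    """Shrink a transformed box to the support of its class inside it."""
    h, w = mask.shape
    x0 = int(np.clip(np.floor(box.xmin), 0, w - 1))
    x1 = int(np.clip(np.ceil(box.xmax), 1, w))
    y0 = int(np.clip(np.floor(box.ymin), 0, h - 1))
    y1 = int(np.clip(np.ceil(box.ymax), 1, h))
    sub = mask[y0:y1, x0:x1] == cls
    if not sub.any():
        return box.clipped(w, h)
    ys, xs = np.nonzero(sub)
    return CornerBox(
        x0 + xs.min(), y0 + ys.min(), x0 + xs.max() + 1.0, y0 + ys.max() + 1.0, box.label
    )


def geometric_augment(
    scene: AnnotatedScene, params: GeometricParams = GeometricParams(), seed: int | None = None
) -> AnnotatedScene:
    """Apply one random affine map consistently to a whole annotated scene.

    Images are resampled bilinearly, masks with nearest-neighbour so labels
    stay integral; boxes are re-tightened to the transformed mask support.
    Samples that push the landmarks or any annotated class out of the frame
    are rejected and redrawn up to ``params.max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.mask.shape

    for _ in range(max(1, params.max_retries)):
        angle = float(rng.uniform(-params.rotate_deg, params.rotate_deg))
        shift = tuple(rng.uniform(-params.shift_px, params.shift_px, size=2))
        zoom = float(rng.uniform(*params.zoom))
        if angle == 0.0 and shift == (0.0, 0.0) and zoom == 1.0:
            return scene  # exact identity; resampling would be a no-op
        tf = _affine_about_center((h, w), angle, shift, zoom)

        def map_pts(pts: np.ndarray) -> np.ndarray:
            return tf(np.atleast_2d(np.asarray(pts, dtype=float)))

        new_left, new_right = map_pts([scene.bmo.left, scene.bmo.right])
        if not (
            0 <= new_left[0] < w and 0 <= new_left[1] < h
            and 0 <= new_right[0] < w and 0 <= new_right[1] < h
            and new_left[0] < new_right[0]
        ):
            continue

        warped = sktransform.warp(
            scene.image.pixels, tf.inverse, order=1, mode="constant", cval=0.0
        )
        mask = sktransform.warp(
            scene.mask.astype(float), tf.inverse, order=0, mode="constant", cval=0.0
        ).astype(np.int64)
        if not ((mask == MASK_BMO).any() and (mask == MASK_LC).any()):
            continue

        boundary = map_pts(scene.lc_boundary)
        order = np.argsort(boundary[:, 0])
        boundary = boundary[order]
        keep = np.concatenate([[True], np.diff(boundary[:, 0]) > 0])
        boundary = boundary[keep]
        inside = (boundary[:, 0] >= 0) & (boundary[:, 0] < w)
        boundary = boundary[inside]
        if len(boundary) < 2:
            continue

        boxes = []
        for box in scene.boxes:
            corners = map_pts(
                [
                    (box.xmin, box.ymin),
                    (box.xmax, box.ymin),
                    (box.xmin, box.ymax),
                    (box.xmax, box.ymax),
                ]
            )
            moved = CornerBox(
                corners[:, 0].min(),
                corners[:, 1].min(),
                corners[:, 0].max(),
                corners[:, 1].max(),
                box.label,
            )
            cls = MASK_BMO if box.label == "BMO" else MASK_LC
            boxes.append(_tighten_box(moved, mask, cls).clipped(w, h))

        return AnnotatedScene(
            image=BScan(np.clip(warped, 0.0, 1.0), scene.image.microns_per_pixel),
            boxes=boxes,
            bmo=BMOPair(left=tuple(new_left), right=tuple(new_right)),
            lc_boundary=boundary,
            mask=mask,
        )

    raise RejectedSampleError(
        f"no valid affine sample found in {params.max_retries} attempts"
    )


def add_noise(
    image: BScan,
    kind: str = "gaussian",
    sigma: float = 0.05,
    length_px: int = 5,
    seed: int | None = None,
) -> BScan:
    """Add acquisition-like noise: additive Gaussian or horizontal motion blur."""
    if kind == "gaussian":
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        if sigma == 0:
            return image
        rng = np.random.default_rng(seed)
        noisy = image.pixels + sigma * rng.standard_normal(image.pixels.shape)
        return BScan(np.clip(noisy, 0.0, 1.0), image.microns_per_pixel)
    if kind == "motion":
        if length_px < 1:
            raise ValueError("motion kernel length must be >= 1")
        if length_px == 1:
            return image
        blurred = ndimage.uniform_filter1d(image.pixels, int(length_px), axis=1, mode="nearest")
        return BScan(np.clip(blurred, 0.0, 1.0), image.microns_per_pixel)
    raise ValueError(f"unknown noise kind {kind!r}; expected 'gaussian' or 'motion'")
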