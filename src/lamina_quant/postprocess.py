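"""Post-processing: from a raw segmentation map to a clean anterior-LC curve.

The segmentation stage yields a per-pixel class map whose LC component is
noisy at the edges and may be interrupted by vessel shadows. Post-processing
(i) erodes the LC class to strip unreliable boundary pixels, (ii) extracts
the anterior (topmost-per-column) LC boundary, and (iii) fits a degree-N
polynomial with ridge regularisation on a standardized abscissa, which
bridges shadow gaps and gives a smooth, everywhere-evaluable curve model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import MASK_LC, BoundaryGapError

logger = logging.getLogger(__name__)

#: Default polynomial degree: one dominant sag with mild asymmetry is well
#: captured by a quartic while staying stiff across occlusion gaps.
DEFAULT_DEGREE = 4
#: Default ridge strength on the standardized abscissa.
DEFAULT_RIDGE = 1e-3


@dataclass
class LCCurveModel:
    """Anterior-LC boundary: ordered samples plus an optional polynomial.

    When ``coefficients`` is None the model is a raw polyline: evaluation
    interpolates between consecutive samples and raises
    :class:`BoundaryGapError` inside gaps wider than ``gap_tolerance`` px —
    the pre-post-processing failure mode under vessel shadows. With fitted
    coefficients the polynomial is evaluable anywhere inside ``x_range``.
    """

    sample_points: np.ndarray  # (N, 2), x strictly increasing
    coefficients: np.ndarray | None = None  # ascending powers in standardized x
    x_mean: float = 0.0
    x_std: float = 1.0
    ridge_lambda: float = 0.0
    x_range: tuple[float, float] = (0.0, 0.0)
    gap_tolerance: float = 2.0

    def __post_init__(self) -> None:
        self.sample_points = np.asarray(self.sample_points, dtype=float)
        if self.sample_points.ndim != 2 or self.sample_points.shape[1] != 2:
            raise ValueError("sample_points must be an (N, 2) array")
        if not np.all(np.diff(self.sample_points[:, 0]) > 0):
            raise ValueError("sample x-coordinates must be strictly increasing")
        if self.x_range == (0.0, 0.0):
            self.x_range = (
                float(self.sample_points[0, 0]),
                float(self.sample_points[-1, 0]),
            )
        if not self.x_range[0] < self.x_range[1]:
            raise ValueError("x_range must be non-degenerate")

    @classmethod
    def from_points(cls, points: np.ndarray, gap_tolerance: float = 2.0) -> "LCCurveModel":
        """Wrap a raw boundary polyline without fitting."""
        return cls(sample_points=np.asarray(points, dtype=float), gap_tolerance=gap_tolerance)

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        x_arr = np.asarray(x, dtype=float)
        lo, hi = self.x_range
        if np.any(x_arr < lo - 1e-9) or np.any(x_arr > hi + 1e-9):
            raise BoundaryGapError(
                f"evaluation at x={x!r} outside the curve validity range [{lo}, {hi}]"
            )
        if self.coefficients is not None:
            z = (x_arr - self.x_mean) / self.x_std
            y = np.polynomial.polynomial.polyval(z, self.coefficients)
            return float(y) if np.isscalar(x) else y
        # raw polyline: linear interpolation, but never across a real gap
        xs = self.sample_points[:, 0]
        flat = np.atleast_1d(x_arr).ravel()
        idx = np.clip(np.searchsorted(xs, flat), 1, len(xs) - 1)
        gap = xs[idx] - xs[idx - 1]
        on_sample = np.isclose(flat[:, None], xs, atol=1e-9).any(axis=1)
        bad = (gap > self.gap_tolerance) & ~on_sample
        if bad.any():
            raise BoundaryGapError(
                f"boundary has no support near x={flat[bad][0]:.1f}"
                f" (gap wider than {self.gap_tolerance} px)"
            )
        y = np.interp(flat, xs, self.sample_points[:, 1])
        if np.isscalar(x) or x_arr.ndim == 0:
            return float(y[0])
        return y.reshape(x_arr.shape)

    def dense_samples(self, step: float = 0.1) -> np.ndarray:
        """Sample the curve on ``x_range`` at the given step (px)."""
        xs = np.arange(self.x_range[0], self.x_range[1] + step / 2, step)
        return np.column_stack([xs, np.asarray(self(xs))])


def erode_mask(mask: np.ndarray, structure_size: int = 3) -> np.ndarray:
    """Binary-erode the LC class with a square element; other classes kept.

    ``structure_size`` 1 is the identity. Eroded-away LC pixels revert to
    background.
    """
    if structure_size < 1:
        raise ValueError("structure_size must be >= 1")
    if structure_size == 1:
        return mask.copy()
    lc = mask == MASK_LC
    eroded = ndimage.binary_erosion(lc, structure=np.ones((structure_size, structure_size)))
    out = mask.copy()
    out[lc & ~eroded] = 0
    return out


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """Anterior LC boundary: the topmost (minimal-y) LC pixel per column.

    Columns without LC pixels are omitted; output x is strictly increasing.
    """
    lc = mask == MASK_LC
    cols = np.nonzero(lc.any(axis=0))[0]
    if len(cols) == 0:
        raise ValueError("mask contains no LC pixels")
    top = lc[:, cols].argmax(axis=0)
    return np.column_stack([cols.astype(float), top.astype(float)])


def fit_lc_curve(
    points: np.ndarray,
    degree: int = DEFAULT_DEGREE,
    ridge_lambda: float = DEFAULT_RIDGE,
    x_range: tuple[float, float] | None = None,
) -> LCCurveModel:
    """Fit y(x) as a degree-N polynomial with ridge on non-intercept terms.

    The abscissa is standardized internally for conditioning; the penalty
    ``ridge_lambda * ||coefficients[1:]||^2`` applies in that standardized
    basis. The fitted model interpolates occlusion gaps anywhere inside
    ``x_range`` (default: the span of the input points).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be non-negative")
    n = len(points)
    if n < degree + 1:
        raise ValueError(f"need at least degree+1={degree + 1} points, got {n}")
    order = np.argsort(points[:, 0])
    points = points[order]
    if not np.all(np.diff(points[:, 0]) > 0):
        raise ValueError("boundary x-coordinates must be strictly increasing")

    x, y = points[:, 0], points[:, 1]
    mu = float(x.mean())
    sd = float(x.std()) or 1.0
    z = (x - mu) / sd
    design = np.vander(z, degree + 1, increasing=True)
    penalty = ridge_lambda * np.diag([0.0] + [1.0] * degree)
    coeffs = np.linalg.solve(design.T @ design + penalty, design.T @ y)

    return LCCurveModel(
        sample_points=points,
        coefficients=coeffs,
        x_mean=mu,
        x_std=sd,
        ridge_lambda=ridge_lambda,
        x_range=x_range if x_range is not None else (float(x[0]), float(x[-1])),
    )
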