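"""Geometric quantification of LCD, LCCD, width W and LCCI in microns.

The BMO reference line joins the two Bruch's membrane termination points.
LCD is the maximum perpendicular distance from that line to the anterior LC
curve, measured between the feet of the perpendiculars dropped from the two
BMO points onto the curve. Those two feet span the width chord, whose
length is W; LCCD is the maximum perpendicular distance from the width
chord down to the curve, and LCCI = LCCD / W × 100.

All geometry is evaluated in micron space (pixel coordinates scaled per
axis), so distances are perpendicular to the chords and the four outputs
are invariant under rigid motions of the scene. A vertical-in-image
measurement mode is available behind the ``mode`` flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import BMOPair, BoundaryGapError, Morphometry, scale_xy
from .postprocess import LCCurveModel


class WidthIntersectionError(ValueError):
    """A perpendicular from a BMO point fails to meet the LC curve."""

    def __init__(self, side: str, detail: str = "") -> None:
        self.side = side
        super().__init__(
            f"perpendicular from the {side} BMO point does not meet the LC curve"
            + (f": {detail}" if detail else "")
        )


@dataclass(frozen=True)
class RefLine:
    """The BMO reference line: its two endpoints in pixel coordinates."""

    p_left: tuple[float, float]
    p_right: tuple[float, float]


def bmo_reference_line(bmo: BMOPair) -> RefLine:
    """Construct the reference line through the two BMO landmarks."""
    if np.allclose(bmo.left, bmo.right):
        raise ValueError("BMO points are coincident; reference line undefined")
    return RefLine(p_left=tuple(bmo.left), p_right=tuple(bmo.right))


def _frame(ref: RefLine, scale) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Chord frame in micron space: (p_l, p_r, unit u, depth normal n, T)."""
    sx, sy = scale_xy(scale)
    p_l = np.array([ref.p_left[0] * sx, ref.p_left[1] * sy])
    p_r = np.array([ref.p_right[0] * sx, ref.p_right[1] * sy])
    chord = p_r - p_l
    t_len = float(np.linalg.norm(chord))
    if t_len == 0:
        raise ValueError("degenerate reference line")
    u = chord / t_len
    n = np.array([-u[1], u[0]])
    if n[1] < 0:
        n = -n  # orient toward increasing image depth
    return p_l, p_r, u, n, t_len


def _curve_um(curve: LCCurveModel, xs_px: np.ndarray, scale) -> np.ndarray:
    sx, sy = scale_xy(scale)
    ys = np.asarray(curve(xs_px), dtype=float)
    return np.column_stack([xs_px * sx, ys * sy])


def _dense_xs(curve: LCCurveModel, step: float) -> np.ndarray:
    lo, hi = curve.x_range
    return np.arange(lo, hi + step / 2, step)


def _foot(
    curve: LCCurveModel, p_l: np.ndarray, u: np.ndarray, target_t: float, side: str, scale,
    step: float,
) -> float:
    """x (px) of the curve point whose chord abscissa equals ``target_t``."""
    sx, sy = scale_xy(scale)
    xs = _dense_xs(curve, step)
    try:
        pts = _curve_um(curve, xs, scale)
    except BoundaryGapError as exc:
        raise WidthIntersectionError(side, str(exc)) from exc
    f = (pts - p_l) @ u - target_t
    sign_change = np.nonzero(np.diff(np.signbit(f)))[0]
    if len(sign_change) == 0:
        raise WidthIntersectionError(side)
    i = int(sign_change[0])
    if curve.coefficients is not None:
        def g(x: float) -> float:
            q = np.array([x * sx, float(curve(x)) * sy])
            return float((q - p_l) @ u) - target_t

        return float(optimize.brentq(g, xs[i], xs[i + 1]))
    # polyline: linear interpolation between bracketing samples
    w = f[i] / (f[i] - f[i + 1])
    return float(xs[i] + w * (xs[i + 1] - xs[i]))


def _max_signed_distance(
    curve: LCCurveModel, origin: np.ndarray, normal: np.ndarray, x_lo: float, x_hi: float,
    scale, step: float,
) -> tuple[float, float]:
    """Maximum of (P(x) − origin)·normal over [x_lo, x_hi]; returns (x*, d*)."""
    sx, sy = scale_xy(scale)
    xs = np.arange(x_lo, x_hi + step / 2, step)
    pts = _curve_um(curve, xs, scale)
    d = (pts - origin) @ normal
    i = int(np.argmax(d))
    x_star, d_star = float(xs[i]), float(d[i])
    if curve.coefficients is not None:
        res = optimize.minimize_scalar(
            lambda x: -float(
                (np.array([x * sx, float(curve(x)) * sy]) - origin) @ normal
            ),
            bounds=(max(x_lo, x_star - 1.0), min(x_hi, x_star + 1.0)),
            method="bounded",
        )
        if -res.fun > d_star:
            x_star, d_star = float(res.x), float(-res.fun)
    return x_star, d_star


def feet_of_perpendiculars(
    curve: LCCurveModel, ref: RefLine, scale, step: float = 0.1
) -> tuple[float, float]:
    """x-positions (px) where the BMO perpendiculars meet the curve."""
    p_l, _, u, _, t_len = _frame(ref, scale)
    x_l = _foot(curve, p_l, u, 0.0, "left", scale, step)
    x_r = _foot(curve, p_l, u, t_len, "right", scale, step)
    if x_l > x_r:
        x_l, x_r = x_r, x_l
    return x_l, x_r


def lcd(
    curve: LCCurveModel, ref: RefLine, scale, step: float = 0.1, mode: str = "perpendicular"
) -> float:
    """Lamina cribrosa depth in μm.

    Maximum perpendicular distance from the BMO reference line to the
    curve, maximized between the two perpendicular feet (dense sampling at
    ``step`` px plus local refinement). ``mode='vertical'`` measures along
    image columns instead.
    """
    p_l, p_r, u, n, _ = _frame(ref, scale)
    x_lo, x_hi = feet_of_perpendiculars(curve, ref, scale, step)
    if mode == "vertical":
        sx, sy = scale_xy(scale)
        xs = np.arange(x_lo, x_hi + step / 2, step)
        chord_y = np.interp(xs * sx, [p_l[0], p_r[0]], [p_l[1], p_r[1]])
        depth = np.asarray(curve(xs), dtype=float) * sy - chord_y
        value = float(depth.max())
    else:
        _, value = _max_signed_distance(curve, p_l, n, x_lo, x_hi, scale, step)
    if value < 0:
        raise ValueError("LC curve lies entirely on the anterior side of the BMO line")
    return value


def lc_width(
    curve: LCCurveModel, bmo: BMOPair, ref: RefLine | None = None, scale=4.0,
    step: float = 0.1,
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Width chord endpoints (px) and its length W in μm.

    The endpoints are the intersections of the curve with the
    perpendiculars to the BMO reference line through each BMO point.
    Raises :class:`WidthIntersectionError` naming the failing side when a
    perpendicular misses the curve (e.g. a raw boundary with a shadow gap).
    """
    ref = ref or bmo_reference_line(bmo)
    sx, sy = scale_xy(scale)
    x_l, x_r = feet_of_perpendiculars(curve, ref, scale, step)
    q_l = np.array([x_l, float(curve(x_l))])
    q_r = np.array([x_r, float(curve(x_r))])
    w_um = float(np.hypot((q_r[0] - q_l[0]) * sx, (q_r[1] - q_l[1]) * sy))
    return (q_l, q_r), w_um


def lccd(
    curve: LCCurveModel,
    width_chord: tuple[np.ndarray, np.ndarray],
    scale,
    step: float = 0.1,
    mode: str = "perpendicular",
) -> float:
    """LC curve depth in μm: maximum depth from the width chord to the curve.

    Zero if the curve never passes below (deeper than) the chord.
    """
    sx, sy = scale_xy(scale)
    q_l, q_r = (np.asarray(q, dtype=float) for q in width_chord)
    a = np.array([q_l[0] * sx, q_l[1] * sy])
    b = np.array([q_r[0] * sx, q_r[1] * sy])
    chord = b - a
    length = float(np.linalg.norm(chord))
    if length == 0:
        raise ValueError("degenerate width chord")
    if mode == "vertical":
        xs = np.arange(min(q_l[0], q_r[0]), max(q_l[0], q_r[0]) + step / 2, step)
        chord_y = np.interp(xs, [q_l[0], q_r[0]], [q_l[1], q_r[1]])
        depth = (np.asarray(curve(xs), dtype=float) - chord_y) * sy
        return float(max(0.0, depth.max()))
    wu = chord / length
    wn = np.array([-wu[1], wu[0]])
    if wn[1] < 0:
        wn = -wn
    _, value = _max_signed_distance(
        curve, a, wn, float(min(q_l[0], q_r[0])), float(max(q_l[0], q_r[0])), scale, step
    )
    return float(max(0.0, value))


def lcci(lccd_um: float, w_um: float) -> float:
    """LC curvature index: LCCD / W × 100 (dimensionless)."""
    if w_um <= 0:
        raise ValueError(f"width must be positive, got {w_um}")
    return lccd_um / w_um * 100.0


def quantify_all(
    bmo: BMOPair, curve: LCCurveModel, scale, step: float = 0.1, mode: str = "perpendicular"
) -> Morphometry:
    """Compose the four measurements; records intermediate geometry.

    The returned record carries the reference-line endpoints, the width
    chord and the measurement mode in its ``geometry`` field for overlay
    plotting.
    """
    ref = bmo_reference_line(bmo)
    lcd_um = lcd(curve, ref, scale, step=step, mode=mode)
    (q_l, q_r), w_um = lc_width(curve, bmo, ref, scale, step=step)
    lccd_um = lccd(curve, (q_l, q_r), scale, step=step, mode=mode)
    return Morphometry(
        lcd=lcd_um,
        lccd=lccd_um,
        width=w_um,
        lcci=lcci(lccd_um, w_um),
        geometry={
            "bmo_left": list(ref.p_left),
            "bmo_right": list(ref.p_right),
            "width_chord": [q_l.tolist(), q_r.tolist()],
            "mode": mode,
        },
    )
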