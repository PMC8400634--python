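"""Synthetic ONH B-scan phantoms with analytically known BMO/LC geometry.

A phantom is deliberately minimal: a bright retinal/RPE band terminating at
the two BMO points, a darker prelaminar cup between them, a bright lamina
cribrosa band whose anterior surface follows a known polynomial, optional
multiplicative speckle, horizontal motion blur and vertical vessel-shadow
bands. Realism is not the goal — exact, analytically computable ground
truth is: every phantom carries its generative curve, so the morphometric
quantities (LCD, LCCD, W, LCCI) can be evaluated directly on the exact
polynomial and compared with what the image-analysis pipeline recovers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage, optimize

from .core import (
    MASK_BMO,
    MASK_LC,
    AnnotatedScene,
    BMOPair,
    BScan,
    CornerBox,
    Morphometry,
    scale_xy,
)

Preset = Literal["normal", "glaucoma"]


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of one phantom B-scan.

    The anterior LC surface is the polynomial ``y(x) = sum c_k x^k`` with
    coefficients ``lc_coeffs`` (ascending powers, image coordinates, y down)
    valid on ``lc_x_range``. The surface must lie strictly below the BMO
    chord between the two BMO points.
    """

    height: int = 500
    width: int = 760
    bmo_left: tuple[float, float] = (209.0, 180.0)
    bmo_right: tuple[float, float] = (551.0, 180.0)
    lc_coeffs: tuple[float, ...] = ()
    lc_x_range: tuple[float, float] = (179.0, 581.0)
    lc_thickness: float = 70.0
    band_thickness: float = 55.0
    bmo_radius: float = 8.0
    intensity_retina: float = 0.85
    intensity_prelaminar: float = 0.35
    intensity_lc: float = 0.70
    intensity_background: float = 0.12
    speckle_sigma: float = 0.10
    motion_blur_px: int = 1
    shadow_count: int = 0
    shadow_factor_range: tuple[float, float] = (2.0, 8.0)
    shadow_width: int = 40
    bmo_box_size: float = 32.0
    lc_box_margin: float = 10.0
    microns_per_pixel: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bmo_left[0] < self.bmo_right[0]:
            raise ValueError("bmo_left must lie left of bmo_right")
        if not (self.lc_x_range[0] < self.bmo_left[0] < self.bmo_right[0] < self.lc_x_range[1]):
            raise ValueError("lc_x_range must bracket both BMO points")
        if len(self.lc_coeffs) < 1:
            raise ValueError("lc_coeffs must define a polynomial")
        for v in (
            self.intensity_retina,
            self.intensity_prelaminar,
            self.intensity_lc,
            self.intensity_background,
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError("band intensities must lie in [0, 1]")
        # the anterior surface must stay strictly below the BMO chord
        xs = np.linspace(self.bmo_left[0], self.bmo_right[0], 512)
        depth = self.curve_y(xs) - self._chord_y(xs)
        if depth.min() <= 0:
            raise ValueError("LC surface must lie strictly below the BMO chord")

    def curve_y(self, x: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the generative anterior-LC polynomial at ``x`` (px)."""
        return np.polynomial.polynomial.polyval(x, np.asarray(self.lc_coeffs))

    def _chord_y(self, x: np.ndarray | float):
        (xl, yl), (xr, yr) = self.bmo_left, self.bmo_right
        return yl + (yr - yl) * (np.asarray(x, dtype=float) - xl) / (xr - xl)

    @staticmethod
    def create(
        *,
        depth_left: float = 90.0,
        depth_right: float = 90.0,
        sag: float = 10.0,
        asym: float = 0.0,
        bmo_left: tuple[float, float] = (209.0, 180.0),
        bmo_right: tuple[float, float] = (551.0, 180.0),
        margin: float = 30.0,
        **kwargs,
    ) -> "PhantomSpec":
        """Build a spec from interpretable geometry parameters.

        ``depth_left``/``depth_right`` are the vertical depths (px) of the
        surface below the BMO chord at the two BMO x-positions, ``sag`` the
        additional mid-chord depth (px) relative to the line joining those
        two surface points, and ``asym`` an antisymmetric cubic term (px).
        For a horizontal BMO chord with ``depth_left == depth_right`` this
        makes LCCD equal ``sag`` exactly.
        """
        (xl, yl), (xr, yr) = bmo_left, bmo_right
        span = xr - xl
        # depth profile in the normalized abscissa q = (x - xl) / span
        # d(q) = dl + (dr - dl) q + 4 sag q (1-q) + asym q (1-q) (2q - 1)
        dl, dr = depth_left, depth_right
        d0 = dl
        d1 = (dr - dl) + 4.0 * sag - asym
        d2 = -4.0 * sag + 3.0 * asym
        d3 = -2.0 * asym
        # compose with q = (x - xl)/span and add the chord line
        q_poly = np.polynomial.Polynomial([-xl / span, 1.0 / span])
        depth_poly = sum(
            c * q_poly**k for k, c in enumerate((d0, d1, d2, d3))
        )
        chord_poly = np.polynomial.Polynomial([yl - (yr - yl) * xl / span, (yr - yl) / span])
        full = chord_poly + depth_poly
        coeffs = tuple(float(c) for c in full.coef)
        return PhantomSpec(
            bmo_left=bmo_left,
            bmo_right=bmo_right,
            lc_coeffs=coeffs,
            lc_x_range=(xl - margin, xr + margin),
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> AnnotatedScene:
    """Render a phantom and its exact ground-truth annotation.

    Deterministic: the same spec (including its ``seed``) yields a
    bitwise-identical scene.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    ys = np.arange(h)[:, None].astype(float)
    xs = np.arange(w)[None, :].astype(float)

    chord_y = np.asarray(spec._chord_y(xs[0]))[None, :]
    curve = np.asarray(spec.curve_y(xs[0]), dtype=float)[None, :]
    xl, xr = spec.bmo_left[0], spec.bmo_right[0]
    x_lo, x_hi = spec.lc_x_range
    in_cup = (xs >= xl) & (xs <= xr)
    in_lc_span = (xs >= x_lo) & (xs <= x_hi)

    img = np.full((h, w), spec.intensity_background)
    # sclera/choroid floor below the band level outside the cup
    below_band = ys >= chord_y
    img[np.broadcast_to(below_band & ~in_cup, (h, w))] = 0.30
    # retinal/RPE band, terminating at the BMO points
    band = (ys >= chord_y - spec.band_thickness) & (ys < chord_y) & ~in_cup
    img[band] = spec.intensity_retina
    # prelaminar tissue: inside the cup, between the chord and the LC surface
    prelam = in_cup & (ys >= chord_y) & (ys < curve)
    img[prelam] = spec.intensity_prelaminar
    # lamina cribrosa band under the anterior surface
    lc_region = in_lc_span & (ys >= curve) & (ys < curve + spec.lc_thickness)
    img[lc_region] = spec.intensity_lc

    if spec.speckle_sigma > 0:
        img = img * (1.0 + spec.speckle_sigma * rng.standard_normal((h, w)))
    if spec.motion_blur_px > 1:
        img = ndimage.uniform_filter1d(img, int(spec.motion_blur_px), axis=1, mode="nearest")
    if spec.shadow_count > 0:
        from .augment import ShadowConfig, vessel_shadow

        cfg = ShadowConfig(
            factor_range=spec.shadow_factor_range,
            shadow_width=spec.shadow_width,
            count=spec.shadow_count,
        )
        shadow_seed = int(rng.integers(0, 2**31 - 1))
        img = vessel_shadow(
            BScan(np.clip(img, 0.0, 1.0), spec.microns_per_pixel), cfg, seed=shadow_seed
        ).pixels

    img = np.clip(img, 0.0, 1.0)

    # ---- ground truth -----------------------------------------------------
    mask = np.zeros((h, w), dtype=np.int64)
    mask[np.broadcast_to(lc_region, (h, w))] = MASK_LC
    for px, py in (spec.bmo_left, spec.bmo_right):
        disk = (xs - px) ** 2 + (ys - py) ** 2 <= spec.bmo_radius**2
        mask[disk] = MASK_BMO

    xs_bound = np.arange(int(np.ceil(x_lo)), int(np.floor(x_hi)) + 1)
    boundary = np.column_stack([xs_bound, np.asarray(spec.curve_y(xs_bound))])

    boxes = []
    half = spec.bmo_box_size / 2.0
    for px, py in (spec.bmo_left, spec.bmo_right):
        boxes.append(
            CornerBox(px - half, py - half, px + half, py + half, "BMO").clipped(w, h)
        )
    m = spec.lc_box_margin
    boxes.append(
        CornerBox(
            boundary[:, 0].min() - m,
            boundary[:, 1].min() - m,
            boundary[:, 0].max() + m,
            boundary[:, 1].max() + m,
            "LC",
        ).clipped(w, h)
    )

    return AnnotatedScene(
        image=BScan(img, microns_per_pixel=spec.microns_per_pixel),
        boxes=boxes,
        bmo=BMOPair(left=spec.bmo_left, right=spec.bmo_right),
        lc_boundary=boundary,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# Analytic (generative-polynomial) morphometry — the ground-truth oracle
# ---------------------------------------------------------------------------

def analytic_morphometry(spec: PhantomSpec, step_px: float = 0.05) -> Morphometry:
    """Evaluate LCD, LCCD, W and LCCI directly on the generative polynomial.

    All geometry is evaluated in micron space (pixel coordinates scaled by
    the per-axis μm/px factors), with perpendicular distances measured
    normal to the respective chords. The maxima are located by dense
    sampling at ``step_px`` followed by bounded local refinement.
    """
    sx, sy = scale_xy(spec.microns_per_pixel)

    def point(x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.stack([x * sx, np.asarray(spec.curve_y(x), dtype=float) * sy], axis=-1)

    p_l = np.array([spec.bmo_left[0] * sx, spec.bmo_left[1] * sy])
    p_r = np.array([spec.bmo_right[0] * sx, spec.bmo_right[1] * sy])
    chord = p_r - p_l
    T = float(np.linalg.norm(chord))
    u = chord / T
    n = np.array([-u[1], u[0]])
    if n[1] < 0:
        n = -n  # depth increases downward

    xs = np.arange(spec.lc_x_range[0], spec.lc_x_range[1] + step_px, step_px)
    pts = point(xs)
    t = (pts - p_l) @ u
    s = (pts - p_l) @ n

    def foot_x(target_t: float, side: str) -> float:
        f = t - target_t
        sign_change = np.nonzero(np.diff(np.signbit(f)))[0]
        if len(sign_change) == 0:
            raise ValueError(f"perpendicular from the {side} BMO point misses the curve")
        i = sign_change[0]
        return float(optimize.brentq(
            lambda x: float((point(x) - p_l) @ u) - target_t, xs[i], xs[i + 1]
        ))

    x_foot_l = foot_x(0.0, "left")
    x_foot_r = foot_x(T, "right")
    q_l, q_r = point(x_foot_l), point(x_foot_r)
    W = float(np.linalg.norm(q_r - q_l))

    between = (xs >= x_foot_l) & (xs <= x_foot_r)

    def refine_max(fun, x0: float, lo: float, hi: float) -> float:
        res = optimize.minimize_scalar(
            lambda x: -fun(x), bounds=(max(lo, x0 - 1.0), min(hi, x0 + 1.0)), method="bounded"
        )
        return float(max(fun(x0), -res.fun))

    # LCD: perpendicular distance from the BMO reference line
    s_bet = s[between]
    x_bet = xs[between]
    i_max = int(np.argmax(s_bet))
    lcd_um = refine_max(
        lambda x: float((point(x) - p_l) @ n), x_bet[i_max], x_foot_l, x_foot_r
    )
    if lcd_um < 0:
        raise ValueError("LC surface lies on the anterior side of the BMO line")

    # LCCD: perpendicular distance from the width chord
    wu = (q_r - q_l) / W
    wn = np.array([-wu[1], wu[0]])
    if wn[1] < 0:
        wn = -wn

    def chord_depth(x: float) -> float:
        return float((point(x) - q_l) @ wn)

    d = (pts[between] - q_l) @ wn
    j_max = int(np.argmax(d))
    lccd_um = max(0.0, refine_max(chord_depth, x_bet[j_max], x_foot_l, x_foot_r))

    lcci = lccd_um / W * 100.0
    return Morphometry(lcd=lcd_um, lccd=lccd_um, width=W, lcci=lcci)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Per-preset parameter ranges (all px at the default 4 μm/px scale). The
#: normal ranges target LCD around 400 μm with a shallow sag; the glaucoma
#: ranges target LCD around 630 μm with a wider opening and deeper sag,
#: mirroring the normal-vs-glaucoma contrast of a typical ONH cohort.
PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        "depth": (80.0, 100.0),
        "sag": (6.0, 14.0),
        "separation": (320.0, 365.0),
        "bmo_y": (165.0, 200.0),
        "tilt_y": (-6.0, 6.0),
        "asym": (-3.0, 3.0),
        "speckle": (0.05, 0.15),
    },
    "glaucoma": {
        "depth": (105.0, 135.0),
        "sag": (28.0, 46.0),
        "separation": (500.0, 560.0),
        "bmo_y": (150.0, 185.0),
        "tilt_y": (-6.0, 6.0),
        "asym": (-6.0, 6.0),
        "speckle": (0.05, 0.15),
    },
}


def draw_spec(
    rng: np.random.Generator,
    preset: Preset = "normal",
    easy: bool = False,
    **overrides,
) -> PhantomSpec:
    """Draw one random valid phantom spec from a preset's parameter ranges.

    ``easy`` narrows the geometric variability and suppresses speckle — the
    regime used for desk-scale training of the miniature networks.
    """
    p = PRESETS[preset]

    def u(lo_hi: tuple[float, float]) -> float:
        return float(rng.uniform(*lo_hi))

    sep = u(p["separation"])
    if easy:
        sep = float(np.mean(p["separation"])) + float(rng.uniform(-10, 10))
    cx = 380.0 + (0.0 if easy else float(rng.uniform(-25, 25)))
    y0 = u(p["bmo_y"]) if not easy else float(np.mean(p["bmo_y"]))
    tilt = 0.0 if easy else u(p["tilt_y"])
    depth_l = u(p["depth"])
    depth_r = depth_l + (0.0 if easy else float(rng.uniform(-8, 8)))
    kwargs = dict(
        depth_left=depth_l,
        depth_right=float(np.clip(depth_r, *p["depth"])),
        sag=u(p["sag"]),
        asym=0.0 if easy else u(p["asym"]),
        bmo_left=(cx - sep / 2.0, y0 - tilt / 2.0),
        bmo_right=(cx + sep / 2.0, y0 + tilt / 2.0),
        speckle_sigma=0.04 if easy else u(p["speckle"]),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    kwargs.update(overrides)
    return PhantomSpec.create(**kwargs)


def make_cohort(
    n: int,
    preset: Preset = "normal",
    seed: int = 0,
    easy: bool = False,
) -> list[tuple[AnnotatedScene, Morphometry]]:
    """Generate ``n`` phantoms with attached analytic ground truth."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = draw_spec(rng, preset=preset, easy=easy)
        out.append((generate_phantom(spec), analytic_morphometry(spec)))
    return out
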