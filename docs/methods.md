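# Methods

This note documents the models, algorithms and design choices behind
`lamina-quant`: a two-stage analysis of optic-nerve-head (ONH) OCT B-scans
that detects the Bruch's membrane opening (BMO) and lamina cribrosa (LC)
regions, segments them per pixel, cleans the anterior LC boundary with a
ridge-regularised polynomial, and quantifies LC depth (LCD), LC curve
depth (LCCD), width (W) and the LC curvature index (LCCI).

## Coordinate and unit conventions

Pixel coordinates are 0-based with x rightward and y downward, so
anatomical "depth below" a reference line means larger y. Boxes are
half-open `[min, max)` when rasterised. The physical scale is a
microns-per-pixel factor (default 4.0 μm/px, isotropic; an `(sx, sy)` pair
is accepted everywhere geometry is computed). The default was chosen once
so that a 500 × 760 px B-scan with a 340 px BMO opening corresponds to a
~1.4 mm opening and a normal-range LCD of ~400 μm — the scale of the ONH
structures the method targets; the device scale of any real dataset should
be configured explicitly.

## Morphometric definitions

Let `p_l`, `p_r` be the BMO landmarks and `C` the anterior LC curve.

* **BMO reference line** — the segment `p_l p_r`, with its unit normal
  oriented toward increasing depth.
* **Width chord and W** — perpendiculars to the reference line dropped
  from each BMO point meet `C` at two feet; the chord joining them has
  length W (μm).
* **LCD** — the maximum perpendicular distance from the reference line to
  `C`, taken between the two feet.
* **LCCD** — the maximum perpendicular distance from the width chord down
  to `C` (0 if the curve never passes below the chord).
* **LCCI** — `LCCD / W × 100`, dimensionless.

Distances are measured perpendicular to the respective chords, not along
image columns: this is what makes all four outputs invariant under rigid
motions of the scene (verified by a rotation test at 3°, agreement within
0.5%). A vertical-in-image mode is available behind the `mode="vertical"`
flag for comparison with column-wise protocols.

Maxima and chord feet are located by dense sampling of the curve at
0.1 px steps followed by bounded local refinement (`scipy.optimize`
`minimize_scalar`/`brentq` on the smooth fitted polynomial); the
refinement tolerance is far below the 1 px scale that matters here.
Reported table values are rounded half-up to 2 decimals; internal
computation is full precision.

## Synthetic phantoms

No patient data ships with the package; every stage is exercised on
phantoms with analytically known geometry. A phantom is deliberately
minimal: a bright retinal/RPE band that terminates at the two BMO points,
a darker prelaminar cup, and a bright LC band whose anterior surface is a
known polynomial `y(x)`, plus multiplicative Gaussian speckle, optional
horizontal box-kernel motion blur and vertical vessel-shadow bands. The
generative surface is parameterised by the depths of its endpoints below
the BMO chord, a mid-chord sag (which equals LCCD exactly for a
horizontal chord with equal endpoint depths), and an antisymmetric cubic
term for mild asymmetry.

Cohort presets draw these parameters uniformly from ranges chosen to
target the two clinical regimes the method is meant to separate: normal
eyes around LCD ≈ 400 μm with LCCI ≈ 3, and glaucomatous eyes around
LCD ≈ 630 μm with LCCI ≈ 7, with wider openings. An `easy` flag narrows
the geometric variability and suppresses speckle; that regime is used for
desk-scale training of the miniature networks.

`analytic_morphometry` evaluates the four quantities directly on the
generative polynomial (dense sampling at 0.05 px plus refinement) and is
the ground-truth oracle for every recovery test. What phantoms do *not*
emulate: speckle statistics of real OCT, curved Bruch's membrane, LC
insertion anatomy, vessel shadows with soft edges, or segmentation
ambiguity at the LC insertion zones. Passing the recovery suites therefore
validates the geometry and learning machinery, not clinical performance on
patient scans.

## Vessel-shadow augmentation

A shadow is a full-height vertical band of width W″ whose start column is
drawn uniformly from `[W″, width − W″]`; all pixels in the band are
multiplied by `1/S` with the shadow factor S drawn uniformly from a
configured range with S ≥ 1, so shadows only ever darken. Defaults: one
band per image, S ∈ [2, 8], W″ = 40 px. Geometric augmentation applies a
single sampled affine map (rotation, shift, zoom about the image center)
consistently to image (bilinear), mask (nearest-neighbour, so labels stay
integral), boxes (re-tightened to the transformed mask support), landmarks
and boundary; samples that push annotation out of the frame are rejected
and redrawn up to a retry budget. The default stage order is geometric →
noise → shadow, configurable.

## Coarse detection

The detector is a single-shot grid predictor: the input (resized to
128 × 128) is divided into an 8 × 8 grid with B = 2 anchor boxes per cell.
Anchor priors come from k-means over the training box sizes with 1 − IoU
as the distance. Box centers decode as `σ(v_x) + g_x` cell offsets and
sizes as `anchor · exp(v)`; encoding inverts this through the logit, with
offsets at a cell edge clamped to `[1e−6, 1 − 1e−6]`.

The objectness loss is the binary cross-entropy between predicted and
ground-truth objectness summed over responsible cells. Training adds three
terms the objectness term alone cannot provide: a sum-of-squared-errors on
the raw offsets (weight 5), a class BCE over responsible cells, and a
down-weighted (0.5) no-object BCE that suppresses background responses —
without the last term a responsible-cells-only loss has no gradient
against spurious detections. Prediction applies sigmoid decoding, a
confidence threshold on objectness × best class probability, and greedy
per-class NMS at IoU 0.5 (a threshold the grid decoder needs to emit
discrete boxes).

The backbone is four 3 × 3 conv/ReLU/maxpool stages (8→16→24→32 channels)
with a 1 × 1 head — deliberately small enough to train on CPU in about a
minute. Trained for 1500 Adam steps (lr 1e−3, batch 4) on 50 easy
phantoms it reaches 100% box recall at IoU ≥ 0.5 on held-out easy
phantoms; the acceptance bar is 90%.

## Fine segmentation

The segmenter consumes 64 × 64 patches tiled (stride 32, optional jitter)
over the detected boxes. The architecture is a 2-level U-Net with
additive attention gates on the skip connections: the skip activation is
multiplied by `σ(ψ(ReLU(θx + φg)))` computed from the skip (θ) and the
upsampled deeper features (φ); with the gate saturated at 1 it reduces to
a plain skip. Base width 8 channels; 3 output classes (background, BMO,
LC).

The training loss is `α · focal + β · GDL` with α = β = 1. The focal term
is `mean(−(1 − P_t)^γ log P_t)` with γ = 2 over the softmax probability of
each pixel's true class (at γ = 0 it reduces exactly to cross-entropy);
the generalized Dice term uses the squared-inverse-volume class weights
`w_l = 1/(Σ_n r_ln)²`, with empty classes given zero weight. Both terms
exist twice: as plain numpy reference functions (the tested definitions)
and as an autodiff graph used for training; a test asserts the two routes
agree.

Both miniature networks run on a small reverse-mode autodiff engine
written on numpy (`lamina_quant.nn`): im2col convolution, 2 × 2 max
pooling, nearest upsampling, channel concat, elementwise ops and Adam.
Gradients are verified against central differences. After `backward()`
the tape is torn down explicitly so the large im2col buffers captured in
backward closures are freed promptly.

Trained for 300 Adam steps (lr 2e−3, batch 12) on ~200 easy-phantom
patches, held-out foreground Dice is ≈ 0.94 (BMO) and ≈ 0.99 (LC); the
acceptance bar is a mean of 0.8.

## Post-processing

The LC class of a (predicted) mask is binary-eroded with a square element
(default 3 × 3) to strip unreliable boundary pixels; the anterior boundary
is the topmost LC pixel per column; and a degree-N polynomial is fitted to
the boundary by ridge regression on a standardized abscissa, minimising
`Σ(y − p(x))² + λ‖coefficients excluding intercept‖²`. Defaults N = 4
(one dominant sag with mild asymmetry) and λ = 1e−3; both are exposed.
Standardising x is a conditioning choice only — with λ = 0 the fit exactly
interpolates polynomial data regardless.

The fitted model is evaluable anywhere inside its validity range, which is
what bridges vessel-shadow dropouts: a raw boundary polyline raises a
boundary-gap error when the width-chord construction needs a point inside
a gap wider than 2 px, while the fitted curve deviates ≤ 2 px from the
generative surface across a simulated 40 px dropout. When a boundary is
extracted from a rasterised mask, the pipeline subtracts
`structure_size // 2 + 0.5` px: half a pixel centers the topmost-pixel
estimate on the true edge, and eroding a solid band lowers its top edge by
a known `structure_size // 2` rows.

## Evaluation metrics

Precision/recall from confusion counts (empty denominators defined as 0),
average precision as the area under the all-point-interpolated
precision–recall curve (precision envelope integrated over recall steps),
and mAP as the mean of per-class APs. Detection matching is greedy by
descending score with one match per ground-truth box at IoU ≥ 0.5.
Landmark errors are L1 = |dx| + |dy| and L2 = √(dx² + dy²) in μm, per side
and combined (mean of sides); absolute values are used because a signed
sum is not a distance. Curve agreement uses the mean |Δy| over the shared
x-support and the symmetric Hausdorff distance. F1 and the Dice
coefficient computed from a single confusion-count set are algebraically
identical and the package asserts that identity. Table aggregation is the
column-wise arithmetic mean computed in decimal space and rounded half-up
to 2 decimals, so means of printed 2-decimal values round the way the
printed tables do.

## Problem sizes

The test and acceptance runs use desk-scale sizes chosen as the smallest
that make each property meaningful: 100 random phantoms for parameter
recovery (max relative error ≤ 2%, LCCI within 0.2), 50 training / 15
test phantoms and 1500 steps for the detector, ~200 training patches and
300 steps for the segmenter, and cohorts of 50 specs per preset for the
normal-vs-glaucoma contrast.

## Known limitations

* Phantom realism is intentionally limited (see above); no claim is made
  about patient data.
* The miniature networks are not the full-scale detector/segmenter a
  clinical deployment would use; they exercise the losses, encodings and
  pipeline plumbing at CPU scale.
* Boundary extraction assumes the anterior LC surface is single-valued in
  x (one topmost pixel per column), which holds for ONH B-scans but not
  for arbitrary shapes.
* The morphometry assumes both width-chord feet exist inside the fitted
  curve's validity range; the width construction reports the failing side
  otherwise rather than extrapolating silently.
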