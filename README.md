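# lamina-quant

Automatic quantification of anterior lamina cribrosa (LC) morphology in
optic-nerve-head (ONH) OCT B-scans.

The lamina cribrosa is the mesh-like collagenous structure inside the
optic nerve head through which retinal ganglion cell axons pass; it
deforms posteriorly as glaucoma progresses, so its depth and curvature are
clinically meaningful structural markers. Measuring them by hand in OCT
B-scans is slow and observer-dependent. This package implements a fully
automatic two-stage analysis for researchers working on ONH morphometry:

1. **Coarse detection** — a YOLO-style grid detector localises the two
   Bruch's membrane opening (BMO) termination points and the LC region as
   bounding boxes.
2. **Fine segmentation** — an attention-gated U-Net classifies 64 × 64
   patches of the detected regions into background / BMO / LC, trained
   with a focal + generalized-Dice composite loss against class imbalance.
3. **Post-processing** — the LC mask is eroded, the anterior (topmost per
   column) LC boundary extracted, and a degree-N polynomial fitted with
   ridge regularisation, which bridges vessel-shadow dropouts.
4. **Quantification** — from the BMO landmarks and the fitted curve:

   * the *BMO reference line* joins the two BMO points;
   * **LCD** (lamina cribrosa depth) = max perpendicular distance from
     the reference line to the anterior LC surface (μm);
   * **W** = length of the chord joining the two points where
     perpendiculars from the BMO landmarks meet the surface (μm);
   * **LCCD** (LC curve depth) = max perpendicular depth from that width
     chord to the surface (μm);
   * **LCCI** (LC curvature index) = `LCCD / W × 100` (dimensionless).

Because patient OCT volumes cannot ship with the code, the package
includes a first-class **phantom generator**: synthetic B-scans with a
bright retinal band terminating at known BMO points, a polynomial anterior
LC surface, speckle, motion blur and vessel shadows — with every
morphometric quantity computable in closed form from the generative
polynomial. All training, recovery and metric guarantees in the test
suite are stated against these analytic phantoms.

The miniature networks run on a small numpy autodiff engine included in
the package (`lamina_quant.nn`), so everything trains on a single CPU in
minutes.

## Worked example

```python
from lamina_quant import (PhantomSpec, generate_phantom,
                          analytic_morphometry, quantify_all)
from lamina_quant.postprocess import fit_lc_curve

# a phantom with a horizontal BMO chord, endpoint depth 90 px and a
# 10 px mid-chord sag at 4 um/px
spec = PhantomSpec.create(depth_left=90, depth_right=90, sag=10, seed=7)
scene = generate_phantom(spec)

truth = analytic_morphometry(spec)           # oracle on the exact polynomial
curve = fit_lc_curve(scene.lc_boundary)      # ridge quartic on the boundary
morph = quantify_all(scene.bmo, curve, spec.microns_per_pixel)

print("analytic: ", {k: round(v, 2) for k, v in truth.as_dict().items()})
print("recovered:", {k: round(v, 2) for k, v in morph.as_dict().items()})
```

prints

```
analytic:  {'LCD_um': 400.0, 'LCCD_um': 40.0, 'W_um': 1368.0, 'LCCI': 2.92}
recovered: {'LCD_um': 400.0, 'LCCD_um': 40.0, 'W_um': 1368.0, 'LCCI': 2.92}
```

The 90 px endpoint depth plus 10 px sag at 4 μm/px gives LCD = 400 μm;
the sag alone is the curve depth (40 μm); the 342 px BMO opening gives
W = 1368 μm; and LCCI = 40/1368 × 100 = 2.92 — a normal-range eye.
Quantifying the rasterised scene instead of the exact polynomial
reproduces these values to well under one pixel-equivalent.

The same flow is available from the shell:

```bash
lamina-quant phantom --n 5 --preset glaucoma --seed 1 --out scratch/phantoms
lamina-quant run --seed 1 --out scratch/run    # full pipeline + report.json
lamina-quant run --dump-config                 # all defaults
```

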