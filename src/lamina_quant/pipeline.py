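"""End-to-end orchestration: phantom/recipe input -> detection ->
segmentation -> post-processing -> quantification -> report.

A single root seed drives every stochastic stage (phantom drawing,
augmentation, network initialisation and batching) through spawned
``numpy.random.SeedSequence`` children, so identical configurations yield
identical reports. The pipeline can run in ground-truth pass-through mode
(no networks; annotations flow straight into post-processing and
quantification) or with the miniature networks trained on a phantom
cohort.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import detect, postprocess, quantify, segment
from .core import (
    MASK_BMO,
    AnnotatedScene,
    BMOPair,
    Morphometry,
    save_morphometry,
)
from .evaluate import aggregate_table, regression_r2
from .phantom import analytic_morphometry, draw_spec, generate_phantom

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Human-readable configuration; keys mirror the stage modules."""

    n_scenes: int = 10
    preset: str = "normal"
    easy: bool = True
    use_networks: bool = False
    train_scenes: int = 50
    detector: dict = field(default_factory=dict)
    segmenter: dict = field(default_factory=dict)
    erosion_size: int = 3
    curve_degree: int = postprocess.DEFAULT_DEGREE
    ridge_lambda: float = postprocess.DEFAULT_RIDGE
    microns_per_pixel: float = 4.0
    measurement_mode: str = "perpendicular"
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _estimate_bmo_from_mask(
    mask: np.ndarray, boxes: list, fallback: BMOPair
) -> BMOPair:
    """BMO landmarks as centroids of the BMO class inside each BMO box."""
    pts = []
    bmo_boxes = sorted((b for b in boxes if b.label == "BMO"), key=lambda b: b.xmin)
    for box in bmo_boxes[:2]:
        y0, y1 = int(max(0, box.ymin)), int(min(mask.shape[0], np.ceil(box.ymax)))
        x0, x1 = int(max(0, box.xmin)), int(min(mask.shape[1], np.ceil(box.xmax)))
        sub = mask[y0:y1, x0:x1] == MASK_BMO
        if sub.any():
            ys, xs = np.nonzero(sub)
            pts.append((x0 + xs.mean(), y0 + ys.mean()))
        else:
            pts.append(((box.xmin + box.xmax) / 2.0, (box.ymin + box.ymax) / 2.0))
    if len(pts) < 2 or not pts[0][0] < pts[1][0]:
        logger.warning("BMO landmark estimation failed; falling back to reference landmarks")
        return fallback
    return BMOPair(left=tuple(pts[0]), right=tuple(pts[1]))


def quantify_scene(
    scene: AnnotatedScene,
    mask: np.ndarray | None = None,
    bmo: BMOPair | None = None,
    lc_box=None,
    erosion_size: int = 3,
    degree: int = postprocess.DEFAULT_DEGREE,
    ridge_lambda: float = postprocess.DEFAULT_RIDGE,
    mode: str = "perpendicular",
) -> Morphometry:
    """Post-process one (predicted or ground-truth) mask and quantify it.

    When ``lc_box`` is given (the detected LC region), LC pixels outside
    it are discarded first: predicted masks can carry stray LC blobs near
    patch borders that would otherwise distort the boundary fit.

    The extracted boundary is shifted up by ``erosion_size // 2 + 0.5`` px:
    half a pixel centers the rasterised topmost-pixel estimate on the true
    surface, and the erosion of a solid band lowers its top edge by a known
    ``structure_size // 2`` rows, which is undone here.
    """
    mask = scene.mask if mask is None else mask
    bmo = scene.bmo if bmo is None else bmo
    if lc_box is not None:
        inside = np.zeros_like(mask, dtype=bool)
        y0, y1 = int(max(0, lc_box.ymin)), int(np.ceil(lc_box.ymax))
        x0, x1 = int(max(0, lc_box.xmin)), int(np.ceil(lc_box.xmax))
        inside[y0:y1, x0:x1] = True
        mask = np.where((mask == postprocess.MASK_LC) & ~inside, 0, mask)
    eroded = postprocess.erode_mask(mask, erosion_size)
    boundary = postprocess.extract_boundary(eroded)
    boundary = boundary - np.array([0.0, erosion_size // 2 + 0.5])
    curve = postprocess.fit_lc_curve(boundary, degree=degree, ridge_lambda=ridge_lambda)
    return quantify.quantify_all(
        bmo, curve, scene.image.microns_per_pixel, mode=mode
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline on a phantom cohort; returns the report dict."""
    t0 = time.time()
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(4)
    logger.info(
        "pipeline start: degree=%d ridge=%g erosion=%d mode=%s",
        config.curve_degree, config.ridge_lambda, config.erosion_size,
        config.measurement_mode,
    )

    rng = np.random.default_rng(seeds[0])
    scenes, truths = [], []
    for _ in range(config.n_scenes):
        spec = draw_spec(
            rng, preset=config.preset, easy=config.easy,
            microns_per_pixel=config.microns_per_pixel,
        )
        scenes.append(generate_phantom(spec))
        truths.append(analytic_morphometry(spec))

    detector = segmenter = None
    if config.use_networks:
        train_rng = np.random.default_rng(seeds[1])
        train_scenes = [
            generate_phantom(draw_spec(train_rng, preset=config.preset, easy=True))
            for _ in range(config.train_scenes)
        ]
        det_cfg = detect.DetectorConfig(**config.detector)
        detector = detect.train_mini_detector(
            train_scenes, det_cfg, seed=int(np.random.default_rng(seeds[2]).integers(2**31))
        )
        patch_sets = [
            segment.extract_patches(s, stride=32, jitter=4, seed=i)
            for i, s in enumerate(train_scenes[: max(5, len(train_scenes) // 4)])
        ]
        merged = segment.PatchSet(
            patches=np.concatenate([p.patches for p in patch_sets]),
            masks=np.concatenate([p.masks for p in patch_sets]),
            offsets=np.concatenate([p.offsets for p in patch_sets]),
            scene_shape=patch_sets[0].scene_shape,
        )
        seg_cfg = segment.SegmenterConfig(**config.segmenter)
        segmenter = segment.train_mini_segmenter(
            merged, seg_cfg, seed=int(np.random.default_rng(seeds[3]).integers(2**31))
        )

    records, failures = [], []
    for i, scene in enumerate(scenes):
        try:
            if config.use_networks:
                preds = detect.predict_boxes(detector, scene)
                boxes = [b for b, _ in preds] or scene.boxes
                mask = segment.predict_mask(segmenter, scene, boxes=boxes)
                bmo = _estimate_bmo_from_mask(mask, boxes, scene.bmo)
                lc_boxes = [b for b in boxes if b.label == "LC"]
                morph = quantify_scene(
                    scene, mask=mask, bmo=bmo,
                    lc_box=lc_boxes[0] if lc_boxes else None,
                    erosion_size=config.erosion_size,
                    degree=config.curve_degree,
                    ridge_lambda=config.ridge_lambda,
                    mode=config.measurement_mode,
                )
            else:
                # ground-truth pass-through: the annotation polyline itself
                # feeds the curve fit; no mask rasterisation error enters
                curve = postprocess.fit_lc_curve(
                    scene.lc_boundary, degree=config.curve_degree,
                    ridge_lambda=config.ridge_lambda,
                )
                morph = quantify.quantify_all(
                    scene.bmo, curve, scene.image.microns_per_pixel,
                    mode=config.measurement_mode,
                )
            records.append(morph)
        except (ValueError, RuntimeError) as exc:
            failures.append({"scene": i, "stage": type(exc).__name__, "error": str(exc)})
            logger.warning("scene %d failed: %s", i, exc)

    report: dict = {
        "config": asdict(config),
        "n_quantified": len(records),
        "failures": failures,
        "per_scene": [m.as_dict() for m in records],
        "truth_per_scene": [t.as_dict() for t in truths],
    }
    if records:
        rows = [[m.lcd, m.lccd, m.width, m.lcci] for m in records]
        mean_row = aggregate_table(rows)
        report["summary"] = dict(zip(["LCD_um", "LCCD_um", "W_um", "LCCI"], mean_row))
    if len(records) == len(truths) and len(records) >= 2:
        pred_lcd = [m.lcd for m in records]
        true_lcd = [t.lcd for t in truths]
        report["agreement"] = {
            "lcd_r2": regression_r2(pred_lcd, true_lcd),
            "max_rel_err_lcd": float(
                np.max(np.abs(np.array(pred_lcd) - true_lcd) / np.array(true_lcd))
            ),
        }
    report["elapsed_s"] = round(time.time() - t0, 2)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        save_morphometry(records, out / "morphometry.csv")
    return report


def make_overlay(scene: AnnotatedScene, morph: Morphometry, path: str | Path) -> None:
    """Save an annotated overlay figure (reference line, width chord)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.imshow(scene.image.pixels, cmap="gray", vmin=0, vmax=1)
    ax.plot(scene.lc_boundary[:, 0], scene.lc_boundary[:, 1], color="teal", lw=1.5)
    geom = morph.geometry or {}
    if "bmo_left" in geom:
        (xl, yl), (xr, yr) = geom["bmo_left"], geom["bmo_right"]
        ax.plot([xl, xr], [yl, yr], color="cyan", lw=1.2)
        ax.plot([xl, xr], [yl, yr], "r.", ms=8)
    if "width_chord" in geom:
        (a, b) = geom["width_chord"]
        ax.plot([a[0], b[0]], [a[1], b[1]], color="magenta", lw=1.2)
    ax.set_title(
        f"LCD={morph.lcd:.1f}um LCCD={morph.lccd:.1f}um W={morph.width:.1f}um "
        f"LCCI={morph.lcci:.2f}"
    )
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(str(path), dpi=110)
    plt.close(fig)
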