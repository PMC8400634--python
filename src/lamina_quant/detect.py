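"""Coarse detection: grid encoding, box encode/decode, losses, mini detector.

The detector follows the single-shot grid paradigm: the image is divided
into G×G cells, each owning B anchor (prior) boxes; the cell containing a
ground-truth box center is responsible for predicting it. Box centers are
regressed as sigmoid offsets within the cell and sizes as log-scale factors
of the anchor priors; objectness is trained with binary cross-entropy.

The trainable model here is a deliberately small convolutional grid
predictor (a few 3x3 conv/pool stages and a 1x1 head) that runs on CPU at
desk scale on phantom scenes; it exercises the full encode/decode/loss/NMS
path rather than a large backbone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as sk_resize

from . import nn
from .core import AnnotatedScene, CenterBox, CornerBox, center_to_corners, corners_to_center

logger = logging.getLogger(__name__)

CLASS_NAMES = ("BMO", "LC")
_EPS = 1e-7


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def iou(a: CornerBox, b: CornerBox) -> float:
    """Intersection-over-union of two corner boxes, in [0, 1]."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def objectness(q: float, iou_val: float) -> float:
    """Objectness score: object indicator times IoU with the ground truth."""
    if q not in (0, 1, 0.0, 1.0):
        raise ValueError(f"object indicator must be 0 or 1, got {q}")
    if not 0.0 <= iou_val <= 1.0:
        raise ValueError(f"IoU must lie in [0, 1], got {iou_val}")
    return float(q) * float(iou_val)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def decode_box(
    raw: tuple[float, float, float, float],
    cell: tuple[int, int],
    anchor: tuple[float, float],
    cell_px: float,
    label: str = "BMO",
) -> CenterBox:
    """Decode raw offsets against a grid cell and anchor prior.

    Center: ``(sigmoid(vx) + gx) * cell_px`` (likewise y); size:
    ``anchor * exp(v)``.
    """
    vx, vy, vw, vh = raw
    gx, gy = cell
    pw, ph = anchor
    if pw <= 0 or ph <= 0:
        raise ValueError("anchor dimensions must be positive")
    return CenterBox(
        xc=(_sigmoid(vx) + gx) * cell_px,
        yc=(_sigmoid(vy) + gy) * cell_px,
        w=pw * np.exp(vw),
        h=ph * np.exp(vh),
        label=label,
    )


def encode_box(
    gt: CenterBox,
    cell: tuple[int, int],
    anchor: tuple[float, float],
    cell_px: float,
) -> tuple[float, float, float, float]:
    """Invert :func:`decode_box` for a ground-truth box.

    The center offset within the cell is inverted through the logit;
    offsets of exactly 0 or 1 are clamped to [eps, 1−eps] (logged).
    """
    gx, gy = cell
    pw, ph = anchor
    if pw <= 0 or ph <= 0:
        raise ValueError("anchor dimensions must be positive")
    ox = gt.xc / cell_px - gx
    oy = gt.yc / cell_px - gy
    if not (0.0 <= ox <= 1.0 and 0.0 <= oy <= 1.0):
        raise ValueError(f"box center offset ({ox:.3f}, {oy:.3f}) lies outside the cell")
    eps = 1e-6
    if ox in (0.0, 1.0) or oy in (0.0, 1.0):
        logger.info("center offset on a cell edge clamped before logit")
    ox = min(max(ox, eps), 1.0 - eps)
    oy = min(max(oy, eps), 1.0 - eps)
    logit = lambda p: float(np.log(p / (1.0 - p)))  # noqa: E731
    return (logit(ox), logit(oy), float(np.log(gt.w / pw)), float(np.log(gt.h / ph)))


# ---------------------------------------------------------------------------
# Grid encoding
# ---------------------------------------------------------------------------

@dataclass
class GridEncoding:
    """Per-cell, per-anchor detection targets or predictions.

    Arrays are indexed ``[gy, gx, b]``: ``offsets`` (…, 4) raw box offsets,
    ``objectness`` in [0, 1], ``responsibility`` ∈ {0, 1} marking the
    anchor slot of the cell containing a ground-truth center, and
    ``class_scores`` (…, n_classes).
    """

    grid_size: int
    boxes_per_cell: int
    anchors: np.ndarray  # (B, 2) px
    offsets: np.ndarray
    objectness: np.ndarray
    responsibility: np.ndarray
    class_scores: np.ndarray

    @classmethod
    def empty(cls, grid_size: int, boxes_per_cell: int, anchors, n_classes: int = 2):
        g, b = grid_size, boxes_per_cell
        return cls(
            grid_size=g,
            boxes_per_cell=b,
            anchors=np.asarray(anchors, dtype=float),
            offsets=np.zeros((g, g, b, 4)),
            objectness=np.zeros((g, g, b)),
            responsibility=np.zeros((g, g, b)),
            class_scores=np.zeros((g, g, b, n_classes)),
        )


def _anchor_iou(wh: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Shape-only IoU of a (w, h) pair against each anchor (co-centered)."""
    inter = np.minimum(wh[0], anchors[:, 0]) * np.minimum(wh[1], anchors[:, 1])
    union = wh[0] * wh[1] + anchors[:, 0] * anchors[:, 1] - inter
    return inter / union


def encode_scene_boxes(
    boxes: list[CornerBox], grid_size: int, anchors: np.ndarray, cell_px: float
) -> GridEncoding:
    """Build the ground-truth grid encoding for one image's boxes."""
    anchors = np.asarray(anchors, dtype=float)
    enc = GridEncoding.empty(grid_size, len(anchors), anchors)
    for box in boxes:
        cb = corners_to_center(box)
        gx = int(np.clip(cb.xc // cell_px, 0, grid_size - 1))
        gy = int(np.clip(cb.yc // cell_px, 0, grid_size - 1))
        b = int(np.argmax(_anchor_iou(np.array([cb.w, cb.h]), anchors)))
        enc.offsets[gy, gx, b] = encode_box(cb, (gx, gy), tuple(anchors[b]), cell_px)
        enc.objectness[gy, gx, b] = 1.0
        enc.responsibility[gy, gx, b] = 1.0
        enc.class_scores[gy, gx, b, CLASS_NAMES.index(box.label)] = 1.0
    return enc


def detection_objectness_loss(pred: GridEncoding, truth: GridEncoding) -> float:
    """Binary cross-entropy of objectness, summed over responsible slots.

    ``Z = Σ U · BCE(r, r′)`` with ``BCE(r, r′) = −[r log r′ +
    (1−r) log(1−r′)]``; predicted scores are clipped to [eps, 1−eps].
    """
    if pred.objectness.shape != truth.objectness.shape:
        raise ValueError("grid shapes do not match")
    r = truth.objectness
    rp = np.clip(pred.objectness, _EPS, 1.0 - _EPS)
    bce = -(r * np.log(rp) + (1.0 - r) * np.log(1.0 - rp))
    return float((truth.responsibility * bce).sum())


# ---------------------------------------------------------------------------
# Anchor priors by dimensional clustering
# ---------------------------------------------------------------------------

def anchors_from_boxes(
    wh: np.ndarray, k: int, seed: int = 0, iters: int = 100
) -> np.ndarray:
    """k-means over box (w, h) pairs with 1−IoU as the distance."""
    wh = np.asarray(wh, dtype=float)
    if len(wh) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(wh)}")
    rng = np.random.default_rng(seed)
    centers = wh[rng.choice(len(wh), size=k, replace=False)].copy()
    for _ in range(iters):
        inter = np.minimum(wh[:, None, 0], centers[None, :, 0]) * np.minimum(
            wh[:, None, 1], centers[None, :, 1]
        )
        union = (wh[:, 0] * wh[:, 1])[:, None] + (centers[:, 0] * centers[:, 1])[None] - inter
        assign = np.argmax(inter / union, axis=1)
        new = centers.copy()
        for j in range(k):
            pts = wh[assign == j]
            if len(pts):
                new[j] = pts.mean(axis=0)
            else:
                new[j] = wh[rng.integers(len(wh))]
        if np.allclose(new, centers):
            break
        centers = new
    return centers[np.argsort(centers[:, 0] * centers[:, 1])]


# ---------------------------------------------------------------------------
# Miniature trainable detector
# ---------------------------------------------------------------------------

@dataclass
class DetectorConfig:
    """Desk-scale training configuration for the mini grid detector."""

    input_size: int = 128
    grid_size: int = 8
    boxes_per_cell: int = 2
    n_classes: int = 2
    channels: tuple[int, ...] = (8, 16, 24, 32)
    learning_rate: float = 1e-3
    batch_size: int = 4
    steps: int = 1500
    lambda_coord: float = 5.0
    lambda_noobj: float = 0.5
    lambda_class: float = 1.0
    conf_threshold: float = 0.3
    nms_iou: float = 0.5
    seed: int = 0

    @property
    def cell_px(self) -> float:
        return self.input_size / self.grid_size


class MiniDetector:
    """A small convolutional grid predictor over resized B-scans."""

    def __init__(self, config: DetectorConfig, anchors: np.ndarray, seed: int = 0):
        self.config = config
        self.anchors = np.asarray(anchors, dtype=float)
        rng = np.random.default_rng(seed)
        chans = (1,) + tuple(config.channels)
        self.params: list[nn.Tensor] = []
        self._convs = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            w = nn.Tensor(nn.he_normal(rng, (cout, cin, 3, 3), cin * 9), requires_grad=True)
            b = nn.Tensor(np.zeros(cout), requires_grad=True)
            self._convs.append((w, b))
            self.params += [w, b]
        out_ch = config.boxes_per_cell * (5 + config.n_classes)
        wh = nn.Tensor(
            nn.he_normal(rng, (out_ch, chans[-1], 1, 1), chans[-1]), requires_grad=True
        )
        bh = nn.Tensor(np.zeros(out_ch), requires_grad=True)
        self._head = (wh, bh)
        self.params += [wh, bh]
        self.history: list[float] = []

    def forward(self, images: np.ndarray) -> nn.Tensor:
        """images (N, S, S) -> raw predictions (N, G, G, B, 5+C)."""
        cfg = self.config
        x = nn.Tensor(images[:, None, :, :])
        for w, b in self._convs:
            x = nn.maxpool2(nn.conv2d(x, w, b).relu())
        x = nn.conv2d(x, *self._head)
        n = images.shape[0]
        return x.reshape(n, cfg.boxes_per_cell, 5 + cfg.n_classes, cfg.grid_size, cfg.grid_size
                         ).transpose(0, 3, 4, 1, 2)


def _resize_scene(scene: AnnotatedScene, size: int) -> tuple[np.ndarray, list[CornerBox]]:
    img = sk_resize(scene.image.pixels, (size, size), anti_aliasing=True)
    h, w = scene.image.pixels.shape
    fx, fy = size / w, size / h
    boxes = [
        CornerBox(b.xmin * fx, b.ymin * fy, b.xmax * fx, b.ymax * fy, b.label)
        for b in scene.boxes
    ]
    return img, boxes


def _targets(enc: GridEncoding, n_classes: int) -> dict[str, np.ndarray]:
    full = np.concatenate(
        [enc.offsets, enc.objectness[..., None], enc.class_scores], axis=-1
    )
    return {"full": full, "resp": enc.responsibility}


def _training_loss(
    model: MiniDetector, out: nn.Tensor, batch_targets: list[dict[str, np.ndarray]]
) -> nn.Tensor:
    cfg = model.config
    t_full = np.stack([t["full"] for t in batch_targets])
    resp = np.stack([t["resp"] for t in batch_targets])
    n_comp = 5 + cfg.n_classes

    coord_mask = np.zeros(n_comp)
    coord_mask[:4] = 1.0
    coord_w = resp[..., None] * coord_mask * cfg.lambda_coord
    sse = (((out - t_full) ** 2.0) * coord_w).sum()

    bce_w = np.zeros_like(t_full)
    bce_w[..., 4] = resp + (1.0 - resp) * cfg.lambda_noobj
    bce_w[..., 5:] = resp[..., None] * cfg.lambda_class
    probs = out.sigmoid() * (1.0 - 2 * _EPS) + _EPS
    bce = -(t_full * probs.log() + (1.0 - t_full) * (1.0 - probs).log())
    total = sse + (bce * bce_w).sum()
    return total * (1.0 / len(batch_targets))


def train_mini_detector(
    scenes: list[AnnotatedScene], config: DetectorConfig | None = None, seed: int = 0
) -> MiniDetector:
    """Train the mini detector on annotated scenes (typically phantoms).

    Anchors are k-means priors over the training boxes; the loss combines
    the objectness binary cross-entropy with offset sum-of-squares and
    class BCE over responsible slots, plus a down-weighted no-object BCE
    term that suppresses background responses.
    """
    if not scenes:
        raise ValueError("empty training dataset")
    cfg = config or DetectorConfig()
    rng = np.random.default_rng(seed)

    images, encodings = [], []
    all_wh = []
    resized = [_resize_scene(s, cfg.input_size) for s in scenes]
    for _, boxes in resized:
        for b in boxes:
            all_wh.append([b.width, b.height])
    anchors = anchors_from_boxes(np.array(all_wh), cfg.boxes_per_cell, seed=seed)

    for img, boxes in resized:
        enc = encode_scene_boxes(boxes, cfg.grid_size, anchors, cfg.cell_px)
        if not enc.responsibility.any():
            raise ValueError("a training scene produced no responsible cells")
        images.append(img)
        encodings.append(_targets(enc, cfg.n_classes))
    images = np.stack(images)

    model = MiniDetector(cfg, anchors, seed=int(rng.integers(0, 2**31 - 1)))
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    n = len(scenes)
    for step in range(cfg.steps):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        out = model.forward(images[idx])
        loss = _training_loss(model, out, [encodings[i] for i in idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.history.append(float(loss.data))
        if step % 100 == 0:
            logger.info("detector step %d loss %.4f", step, float(loss.data))
    return model


def _nms(cands: list[tuple[CornerBox, float]], iou_thr: float) -> list[tuple[CornerBox, float]]:
    kept: list[tuple[CornerBox, float]] = []
    for box, score in sorted(cands, key=lambda bs: -bs[1]):
        if all(iou(box, k) < iou_thr for k, _ in kept if k.label == box.label):
            kept.append((box, score))
    return kept


def predict_boxes(
    model: MiniDetector, scene_or_image, conf_threshold: float | None = None
) -> list[tuple[CornerBox, float]]:
    """Detect boxes on one B-scan; returns (box, score) in image coordinates.

    Applies sigmoid decoding, confidence thresholding (score = objectness ×
    best class probability) and greedy per-class NMS.
    """
    cfg = model.config
    if isinstance(scene_or_image, AnnotatedScene):
        pixels = scene_or_image.image.pixels
    else:
        pixels = scene_or_image.pixels if hasattr(scene_or_image, "pixels") else scene_or_image
    thr = cfg.conf_threshold if conf_threshold is None else conf_threshold
    h, w = pixels.shape
    img = sk_resize(pixels, (cfg.input_size, cfg.input_size), anti_aliasing=True)
    out = model.forward(img[None]).data[0]  # (G, G, B, 5+C)
    obj = _sigmoid(out[..., 4])
    cls = _sigmoid(out[..., 5:])
    score = obj * cls.max(axis=-1)
    fx, fy = w / cfg.input_size, h / cfg.input_size

    cands: list[tuple[CornerBox, float]] = []
    for gy, gx, b in zip(*np.nonzero(score >= thr)):
        label = CLASS_NAMES[int(np.argmax(cls[gy, gx, b]))]
        cb = decode_box(
            tuple(out[gy, gx, b, :4]), (gx, gy), tuple(model.anchors[b]), cfg.cell_px, label
        )
        corner = center_to_corners(cb)
        corner = CornerBox(
            corner.xmin * fx, corner.ymin * fy, corner.xmax * fx, corner.ymax * fy, label
        )
        try:
            corner = corner.clipped(w, h)
        except Exception:
            continue
        cands.append((corner, float(score[gy, gx, b])))
    return _nms(cands, cfg.nms_iou)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_detector(model: MiniDetector, path: str | Path) -> None:
    """Save weights, anchors and config to an .npz checkpoint."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params)}
    arrays["anchors"] = model.anchors
    arrays["config_json"] = np.array(json.dumps(asdict(model.config)))
    np.savez(str(path), **arrays)


def load_detector(path: str | Path) -> MiniDetector:
    data = np.load(str(path), allow_pickle=False)
    cfg_dict = json.loads(str(data["config_json"]))
    cfg_dict["channels"] = tuple(cfg_dict["channels"])
    cfg = DetectorConfig(**cfg_dict)
    model = MiniDetector(cfg, data["anchors"], seed=0)
    for i, p in enumerate(model.params):
        p.data = data[f"param_{i}"]
    return model
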