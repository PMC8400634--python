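"""Grid detection primitives: IoU, box encode/decode, objectness loss."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamina_quant.core import CenterBox, CornerBox
from lamina_quant.detect import (
    DetectorConfig,
    GridEncoding,
    MiniDetector,
    anchors_from_boxes,
    decode_box,
    detection_objectness_loss,
    encode_box,
    encode_scene_boxes,
    iou,
    load_detector,
    objectness,
    predict_boxes,
    save_detector,
)


def rasterized_iou(a: CornerBox, b: CornerBox) -> float:
    """Brute-force pixel-counting IoU for integer boxes (half-open)."""
    xs = range(int(min(a.xmin, b.xmin)), int(max(a.xmax, b.xmax)))
    ys = range(int(min(a.ymin, b.ymin)), int(max(a.ymax, b.ymax)))
    inter = union = 0
    for x in xs:
        for y in ys:
            in_a = a.xmin <= x < a.xmax and a.ymin <= y < a.ymax
            in_b = b.xmin <= x < b.xmax and b.ymin <= y < b.ymax
            inter += in_a and in_b
            union += in_a or in_b
    return inter / union if union else 0.0


def random_int_box(rng, size=40):
    x0, y0 = rng.integers(0, size, 2)
    w, h = rng.integers(1, size // 2, 2)
    return CornerBox(float(x0), float(y0), float(x0 + w), float(y0 + h))


class TestIoU:
    def test_identical_boxes(self):
        b = CornerBox(0, 0, 10, 10)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(CornerBox(0, 0, 10, 10), CornerBox(20, 20, 30, 30)) == 0.0

    def test_half_overlap_case(self):
        assert iou(CornerBox(0, 0, 10, 10), CornerBox(5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_matches_rasterized_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = random_int_box(rng), random_int_box(rng)
            assert iou(a, b) == pytest.approx(rasterized_iou(a, b), abs=1e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = random_int_box(rng), random_int_box(rng)
            assert iou(a, b) == pytest.approx(iou(b, a), abs=1e-12)


class TestObjectness:
    @pytest.mark.parametrize("q, val, expected", [(1, 1.0, 1.0), (0, 0.7, 0.0), (1, 1 / 3, 1 / 3)])
    def test_product_rule(self, q, val, expected):
        assert objectness(q, val) == pytest.approx(expected)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            objectness(0.5, 0.5)
        with pytest.raises(ValueError):
            objectness(1, 1.5)


class TestEncodeDecode:
    def test_zero_offsets_center_of_cell_anchor_size(self):
        cb = decode_box((0, 0, 0, 0), cell=(2, 3), anchor=(4, 6), cell_px=1.0)
        assert (cb.xc, cb.yc) == (2.5, 3.5)
        assert (cb.w, cb.h) == (4.0, 6.0)

    def test_anchor_sized_box_encodes_to_zero_logs(self):
        gt = CenterBox(2.5, 3.5, 4.0, 6.0)
        v = encode_box(gt, cell=(2, 3), anchor=(4, 6), cell_px=1.0)
        assert v[0] == pytest.approx(0.0) and v[1] == pytest.approx(0.0)
        assert v[2] == pytest.approx(0.0) and v[3] == pytest.approx(0.0)

    @settings(max_examples=150, deadline=None)
    @given(
        ox=st.floats(0.01, 0.99),
        oy=st.floats(0.01, 0.99),
        w=st.floats(0.5, 50),
        h=st.floats(0.5, 50),
        cell_px=st.floats(4, 64),
    )
    def test_encode_decode_round_trip(self, ox, oy, w, h, cell_px):
        cell, anchor = (3, 5), (8.0, 12.0)
        gt = CenterBox((3 + ox) * cell_px, (5 + oy) * cell_px, w, h)
        decoded = decode_box(encode_box(gt, cell, anchor, cell_px), cell, anchor, cell_px)
        assert decoded.xc == pytest.approx(gt.xc, abs=1e-6)
        assert decoded.yc == pytest.approx(gt.yc, abs=1e-6)
        assert decoded.w == pytest.approx(gt.w, rel=1e-9)
        assert decoded.h == pytest.approx(gt.h, rel=1e-9)

    def test_edge_offset_clamped_not_failing(self):
        gt = CenterBox(3 * 16.0, 5 * 16.0, 4, 4)  # offset exactly 0
        v = encode_box(gt, (3, 5), (4, 4), 16.0)
        assert np.isfinite(v).all()

    def test_center_outside_cell_rejected(self):
        with pytest.raises(ValueError):
            encode_box(CenterBox(100, 100, 4, 4), (0, 0), (4, 4), 16.0)


def scalar_loop_loss(pred: GridEncoding, truth: GridEncoding) -> float:
    eps = 1e-7
    total = 0.0
    g, b = truth.grid_size, truth.boxes_per_cell
    for i in range(g):
        for j in range(g):
            for k in range(b):
                u = truth.responsibility[i, j, k]
                r = truth.objectness[i, j, k]
                rp = min(max(pred.objectness[i, j, k], eps), 1 - eps)
                total += u * -(r * np.log(rp) + (1 - r) * np.log(1 - rp))
    return total


class TestObjectnessLoss:
    def _random_grids(self, rng, g=4, b=2):
        anchors = rng.uniform(2, 10, size=(b, 2))
        pred = GridEncoding.empty(g, b, anchors)
        truth = GridEncoding.empty(g, b, anchors)
        pred.objectness = rng.random((g, g, b))
        truth.objectness = (rng.random((g, g, b)) > 0.7).astype(float)
        truth.responsibility = truth.objectness.copy()
        return pred, truth

    def test_perfect_prediction_near_zero(self):
        rng = np.random.default_rng(2)
        pred, truth = self._random_grids(rng)
        pred.objectness = truth.objectness.copy()
        assert detection_objectness_loss(pred, truth) <= 32 * 1e-6

    def test_single_cell_half_confidence(self):
        anchors = [(4, 4)]
        pred = GridEncoding.empty(2, 1, anchors)
        truth = GridEncoding.empty(2, 1, anchors)
        truth.objectness[0, 0, 0] = 1.0
        truth.responsibility[0, 0, 0] = 1.0
        pred.objectness[0, 0, 0] = 0.5
        assert detection_objectness_loss(pred, truth) == pytest.approx(np.log(2), rel=1e-9)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pred, truth = self._random_grids(rng, g=int(rng.integers(2, 5)), b=int(rng.integers(1, 3)))
            assert detection_objectness_loss(pred, truth) == pytest.approx(
                scalar_loop_loss(pred, truth), abs=1e-9
            )

    def test_monotone_in_predicted_confidence(self):
        anchors = [(4, 4)]
        truth = GridEncoding.empty(2, 1, anchors)
        truth.objectness[1, 1, 0] = truth.responsibility[1, 1, 0] = 1.0
        losses = []
        for conf in (0.2, 0.5, 0.9, 0.99):
            pred = GridEncoding.empty(2, 1, anchors)
            pred.objectness[1, 1, 0] = conf
            losses.append(detection_objectness_loss(pred, truth))
        assert np.all(np.diff(losses) < 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detection_objectness_loss(
                GridEncoding.empty(2, 1, [(4, 4)]), GridEncoding.empty(3, 1, [(4, 4)])
            )


class TestAnchorsAndEncoding:
    def test_kmeans_recovers_two_distinct_shapes(self):
        rng = np.random.default_rng(4)
        small = rng.normal([10, 12], 0.5, size=(50, 2))
        large = rng.normal([60, 40], 1.0, size=(50, 2))
        anchors = anchors_from_boxes(np.vstack([small, large]), k=2, seed=0)
        assert np.allclose(anchors[0], [10, 12], atol=1.0)
        assert np.allclose(anchors[1], [60, 40], atol=2.0)

    def test_insufficient_boxes_for_kmeans_rejected(self):
        with pytest.raises(ValueError):
            anchors_from_boxes(np.array([[10.0, 10.0]]), k=2)

    def test_scene_encoding_marks_responsible_cells(self):
        boxes = [CornerBox(10, 10, 42, 42, "BMO"), CornerBox(60, 70, 120, 110, "LC")]
        anchors = np.array([[32.0, 32.0], [60.0, 40.0]])
        enc = encode_scene_boxes(boxes, grid_size=8, anchors=anchors, cell_px=16.0)
        assert enc.responsibility.sum() == 2
        assert enc.objectness.sum() == 2
        # box centers (26, 26) and (90, 90) fall in cells (1, 1) and (5, 5)
        assert enc.responsibility[1, 1].any()
        assert enc.responsibility[5, 5].any()


class TestPredictionInterface:
    def _model(self):
        return MiniDetector(DetectorConfig(), anchors=np.array([[6.0, 9.0], [70.0, 12.0]]), seed=0)

    def test_confidence_threshold_one_yields_no_boxes(self, default_scene):
        model = self._model()
        assert predict_boxes(model, default_scene, conf_threshold=1.0) == []

    def test_predicted_boxes_clipped_to_frame(self, default_scene):
        model = self._model()
        for box, score in predict_boxes(model, default_scene, conf_threshold=0.0)[:20]:
            assert 0 <= box.xmin < box.xmax <= default_scene.image.width
            assert 0 <= box.ymin < box.ymax <= default_scene.image.height
            assert 0.0 <= score <= 1.0

    def test_checkpoint_round_trip(self, tmp_path, default_scene):
        model = self._model()
        save_detector(model, tmp_path / "det.npz")
        loaded = load_detector(tmp_path / "det.npz")
        a = predict_boxes(model, default_scene, conf_threshold=0.0)
        b = predict_boxes(loaded, default_scene, conf_threshold=0.0)
        assert [(x.label, x.xmin, x.ymin) for x, _ in a] == [
            (x.label, x.xmin, x.ymin) for x, _ in b
        ]

    def test_empty_training_set_rejected(self):
        from lamina_quant.detect import train_mini_detector

        with pytest.raises(ValueError):
            train_mini_detector([], DetectorConfig())
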