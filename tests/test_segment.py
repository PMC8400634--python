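"""Patch extraction, focal/GDL losses and the attention U-Net building blocks."""

import numpy as np
import pytest

from lamina_quant import nn
from lamina_quant.core import CornerBox
from lamina_quant.segment import (
    LossConfig,
    MiniAttentionUNet,
    SegmenterConfig,
    combined_loss,
    extract_patches,
    focal_loss,
    generalized_dice_loss,
    one_hot,
    segmentation_loss_graph,
    stitch_probs,
)


class TestExtractPatches:
    def test_single_patch_for_exact_box(self, default_scene):
        box = [CornerBox(100, 100, 164, 164, "LC")]
        ps = extract_patches(default_scene, boxes=box, stride=64, jitter=0)
        assert len(ps) == 1
        assert tuple(ps.offsets[0]) == (100, 100)
        assert np.array_equal(
            ps.patches[0], default_scene.image.pixels[100:164, 100:164]
        )

    def test_tiling_arithmetic(self, default_scene):
        box = [CornerBox(100, 100, 228, 164, "LC")]  # 128 x 64
        ps = extract_patches(default_scene, boxes=box, stride=64, jitter=0)
        assert len(ps) == 2

    def test_jitter_deterministic_under_seed(self, default_scene):
        a = extract_patches(default_scene, stride=32, jitter=5, seed=4)
        b = extract_patches(default_scene, stride=32, jitter=5, seed=4)
        assert np.array_equal(a.offsets, b.offsets)

    def test_masks_aligned_with_patches(self, default_scene):
        ps = extract_patches(default_scene, stride=32, jitter=0)
        i = len(ps) // 2
        x0, y0 = ps.offsets[i]
        assert np.array_equal(ps.masks[i], default_scene.mask[y0 : y0 + 64, x0 : x0 + 64])

    def test_small_box_padded(self, default_scene):
        box = [CornerBox(5, 5, 30, 30, "BMO")]
        ps = extract_patches(default_scene, boxes=box, stride=64, jitter=0)
        assert len(ps) == 1 and ps.patches[0].shape == (64, 64)


class TestFocalLoss:
    def test_perfect_prediction_is_zero(self):
        assert focal_loss(np.ones(10), gamma=2.0) == pytest.approx(0.0, abs=1e-6)

    def test_gamma_zero_is_cross_entropy(self):
        rng = np.random.default_rng(0)
        pt = rng.uniform(0.01, 0.99, size=500)
        assert focal_loss(pt, 0.0) == pytest.approx(float(np.mean(-np.log(pt))), abs=1e-12)

    def test_hand_evaluated_single_pixel(self):
        assert focal_loss(np.array([0.5]), gamma=2.0) == pytest.approx(0.25 * np.log(2), rel=1e-12)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([0.5]), gamma=-1.0)


def gdl_scalar_loop(pred, truth, weights):
    num = den = 0.0
    for l in range(pred.shape[-1]):
        sn = sd = 0.0
        for n in range(pred.shape[0]):
            sn += truth[n, l] * pred[n, l]
            sd += truth[n, l] + pred[n, l]
        num += weights[l] * sn
        den += weights[l] * sd
    return 1.0 - 2.0 * num / den


class TestGeneralizedDice:
    def test_perfect_binary_overlap_is_zero(self):
        truth = one_hot(np.array([[0, 1], [1, 0]]), 2)
        assert generalized_dice_loss(truth, truth, "auto") == pytest.approx(0.0)

    def test_total_disjointness_is_one(self):
        truth = one_hot(np.array([0, 0, 1, 1]), 2)
        pred = one_hot(np.array([1, 1, 0, 0]), 2)
        assert generalized_dice_loss(pred, truth, "auto") == pytest.approx(1.0)

    def test_soft_two_by_two_matches_scalar_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pred = rng.dirichlet(np.ones(2), size=4)
            truth = one_hot(rng.integers(0, 2, 4), 2)
            w = rng.uniform(0.1, 2.0, size=2)
            assert generalized_dice_loss(pred, truth, tuple(w)) == pytest.approx(
                gdl_scalar_loop(pred, truth, w), abs=1e-9
            )

    def test_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(2)
        pred = rng.dirichlet(np.ones(3), size=100)
        truth = one_hot(rng.integers(0, 3, 100), 3)
        base = generalized_dice_loss(pred, truth, "auto")
        perm = rng.permutation(100)
        assert generalized_dice_loss(pred[perm], truth[perm], "auto") == pytest.approx(base)
        assert 0.0 <= base <= 1.0

    def test_empty_image_defined_as_zero(self):
        pred = np.zeros((4, 2))
        truth = np.zeros((4, 2))
        assert generalized_dice_loss(pred, truth, (1.0, 1.0)) == 0.0


class TestCombinedLoss:
    def test_zero_parts_zero_sum(self):
        assert combined_loss(0.0, 0.0) == 0.0

    def test_unit_weights_exact_sum(self):
        assert combined_loss(0.2, 0.3, LossConfig(alpha=1.0, beta=1.0)) == pytest.approx(0.5)

    def test_linear_in_alpha(self):
        l1 = combined_loss(0.4, 0.1, LossConfig(alpha=1.0, beta=2.0))
        l2 = combined_loss(0.4, 0.1, LossConfig(alpha=3.0, beta=2.0))
        assert l2 - l1 == pytest.approx(2 * 0.4)


class TestLossGraph:
    def test_graph_matches_numpy_losses(self):
        rng = np.random.default_rng(3)
        logits = rng.standard_normal((2, 3, 64, 64))
        truth = one_hot(rng.integers(0, 3, (2, 64, 64)), 3)
        cfg = LossConfig(gamma=2.0)
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        pt = (probs * np.moveaxis(truth, -1, 1)).sum(axis=1)
        expected = combined_loss(
            focal_loss(pt, cfg.gamma),
            generalized_dice_loss(np.moveaxis(probs, 1, -1), truth, cfg.class_weights),
            cfg,
        )
        graph = float(segmentation_loss_graph(nn.Tensor(logits), truth, cfg).data)
        assert graph == pytest.approx(expected, abs=1e-5)


class TestAttentionGate:
    def test_saturated_gate_passes_skip_through(self):
        """With the gate's output conv biased strongly positive, the sigmoid
        saturates at 1 and the gated skip equals the plain skip."""
        model = MiniAttentionUNet(SegmenterConfig(base_channels=4), seed=0)
        (tw, tb), (pw, pb), (sw, sb) = model.att1
        sb.data[:] = 50.0  # force sigmoid(psi) -> 1
        sw.data[:] = 0.0
        skip = nn.Tensor(np.random.default_rng(4).random((1, 4, 16, 16)))
        gating = nn.Tensor(np.random.default_rng(5).random((1, 8, 16, 16)))
        gated = model._gate(skip, gating, model.att1)
        assert np.allclose(gated.data, skip.data, atol=1e-9)


class TestStitching:
    def test_overlap_averaging_and_argmax(self):
        probs = np.zeros((2, 3, 64, 64))
        probs[0, 1] = 1.0  # patch 0 votes BMO
        probs[1, 2] = 1.0  # patch 1 votes LC
        acc = stitch_probs(probs, np.array([[0, 0], [32, 0]]), (64, 96))
        # exclusive regions keep their vote; overlap averages to a tie
        assert acc[1, 0, 0] == 1.0
        assert acc[2, 0, 80] == 1.0
        assert acc[1, 0, 40] == pytest.approx(0.5)
        assert acc[2, 0, 40] == pytest.approx(0.5)


class TestSegmenterInterface:
    def test_checkpoint_round_trip(self, tmp_path):
        from lamina_quant.segment import load_segmenter, predict_patch_probs, save_segmenter

        model = MiniAttentionUNet(SegmenterConfig(base_channels=4), seed=2)
        rng = np.random.default_rng(0)
        patches = rng.random((3, 64, 64))
        save_segmenter(model, tmp_path / "seg.npz")
        loaded = load_segmenter(tmp_path / "seg.npz")
        assert np.allclose(
            predict_patch_probs(model, patches), predict_patch_probs(loaded, patches)
        )

    def test_empty_patchset_rejected(self):
        from lamina_quant.segment import PatchSet, train_mini_segmenter

        empty = PatchSet(
            patches=np.zeros((0, 64, 64)),
            masks=np.zeros((0, 64, 64), dtype=int),
            offsets=np.zeros((0, 2), dtype=int),
            scene_shape=(500, 760),
        )
        with pytest.raises(ValueError):
            train_mini_segmenter(empty)
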