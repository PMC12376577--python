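"""Loss and metric definitions against brute-force per-pixel oracles."""

import numpy as np
import pytest

from strain2scar.losses import (CompositeLossTerms, bce_grad, bce_loss,
                                binarize, composite_loss, dsc_grad, dsc_loss,
                                evaluate, iou_grad, iou_loss, mse_loss)


def brute_bce(p, y, eps=1e-7):
    total = 0.0
    for pi, yi in zip(p.ravel(), y.ravel()):
        pi = min(max(pi, eps), 1 - eps)
        total += -(yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
    return total / p.size


def brute_dsc_loss(p, y, delta=1e-6):
    num = 2 * sum(pi * yi for pi, yi in zip(p.ravel(), y.ravel())) + delta
    den = p.sum() + y.sum() + delta
    return 1 - num / den


def brute_iou_loss(p, y, delta=1e-6):
    inter = sum(pi * yi for pi, yi in zip(p.ravel(), y.ravel())) + delta
    union = sum(pi + yi - pi * yi
                for pi, yi in zip(p.ravel(), y.ravel())) + delta
    return 1 - inter / union


@pytest.fixture
def random_instance():
    rng = np.random.default_rng(0)
    p = rng.random((4, 4))
    y = (rng.random((4, 4)) > 0.5).astype(float)
    return p, y


class TestBCE:
    def test_half_probability(self):
        p = np.full((4, 4), 0.5)
        y = np.zeros((4, 4))
        assert np.isclose(bce_loss(p, y), np.log(2))

    def test_confident_correct(self):
        p = np.full((3, 3), 0.9)
        y = np.ones((3, 3))
        assert np.isclose(bce_loss(p, y), -np.log(0.9))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        size = rng.integers(4, 17)
        p = rng.random((size, size))
        y = (rng.random((size, size)) > 0.5).astype(float)
        assert abs(bce_loss(p, y) - brute_bce(p, y)) < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((4, 4)), np.zeros((4, 5)))


class TestDiceIoU:
    def test_perfect_binary_prediction(self):
        y = np.zeros((6, 6))
        y[2:4, 2:4] = 1
        assert dsc_loss(y, y) < 1e-5
        assert iou_loss(y, y) < 1e-5

    def test_disjoint_binary_masks(self):
        p = np.zeros((6, 6))
        p[0, 0] = 1
        y = np.zeros((6, 6))
        y[5, 5] = 1
        assert dsc_loss(p, y) > 1 - 1e-5
        assert iou_loss(p, y) > 1 - 1e-5

    def test_iou_half_overlap_formula(self):
        # |P| = |G| = 100, overlap 50 -> IoU loss = 1 - 1/3
        p = np.zeros((20, 20))
        y = np.zeros((20, 20))
        p.ravel()[:100] = 1
        y.ravel()[50:150] = 1
        assert np.isclose(iou_loss(p, y), 2.0 / 3.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_soft_values_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed + 10)
        p = rng.random((3, 3))
        y = (rng.random((3, 3)) > 0.4).astype(float)
        assert abs(dsc_loss(p, y) - brute_dsc_loss(p, y)) < 1e-10
        assert abs(iou_loss(p, y) - brute_iou_loss(p, y)) < 1e-10


class TestGradients:
    @pytest.mark.parametrize("loss_fn,grad_fn", [
        (bce_loss, bce_grad), (dsc_loss, dsc_grad), (iou_loss, iou_grad)])
    def test_matches_central_differences(self, loss_fn, grad_fn,
                                         random_instance):
        p, y = random_instance
        p = 0.2 + 0.6 * p  # keep away from the clipping boundary
        g = grad_fn(p, y)
        eps = 1e-6
        for i in range(4):
            for j in range(4):
                pp = p.copy()
                pp[i, j] += eps
                pm = p.copy()
                pm[i, j] -= eps
                fd = (loss_fn(pp, y) - loss_fn(pm, y)) / (2 * eps)
                assert abs(fd - g[i, j]) < 1e-5


class TestCompositeLoss:
    def test_perfect_predictions_zero(self):
        y = (np.random.default_rng(1).random((2, 4, 4)) > 0.5).astype(float)
        terms = composite_loss(y, y, y, y, weights=(), l2_rate=0.0)
        assert terms.total == 0.0

    def test_l2_penalty_linearity(self):
        rng = np.random.default_rng(2)
        w = [rng.standard_normal((3, 3))]
        p = rng.random((1, 4, 4))
        y = (rng.random((1, 4, 4)) > 0.5).astype(float)
        t1 = composite_loss(p, y, None, None, weights=w, l2_rate=1e-3)
        t2 = composite_loss(p, y, None, None, weights=w, l2_rate=2e-3)
        assert np.isclose(t2.l2_penalty, 2 * t1.l2_penalty)

    def test_matches_hand_computation(self):
        p_l = np.array([[[0.8, 0.2], [0.1, 0.9]], [[0.5, 0.5], [0.0, 1.0]]])
        y_l = np.array([[[1.0, 0.0], [0.0, 1.0]], [[1.0, 0.0], [0.0, 1.0]]])
        p_h = np.array([[[0.6, 0.4], [0.4, 0.6]]])
        y_h = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        terms = composite_loss(p_l, y_l, p_h, y_h, weights=(), l2_rate=0.0)
        # MSE over all low-fidelity pixels (two samples, mean per pixel)
        mse_l_hand = np.mean((p_l - y_l) ** 2)
        mse_h_hand = np.mean((p_h - y_h) ** 2)
        assert np.isclose(terms.mse_l, mse_l_hand)
        assert np.isclose(terms.mse_h, mse_h_hand)
        assert np.isclose(terms.total, mse_l_hand + mse_h_hand)
        assert terms.n_l == 2 and terms.n_h == 1

    def test_both_batches_empty_rejected(self):
        with pytest.raises(ValueError):
            composite_loss(None, None, None, None)


class TestBinarize:
    def test_strict_threshold(self):
        p = np.full((4, 4), 0.5)
        assert binarize(p, 0.5).sum() == 0

    def test_binary_input_identity(self):
        y = (np.random.default_rng(3).random((5, 5)) > 0.5).astype(float)
        for thr in (0.2, 0.5, 0.8):
            assert np.array_equal(binarize(y, thr), y.astype(np.uint8))

    def test_monotone_in_threshold(self):
        p = np.random.default_rng(4).random((8, 8))
        low = binarize(p, 0.3).sum()
        high = binarize(p, 0.7).sum()
        assert high <= low

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 1.5)


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.zeros((8, 8), dtype=np.uint8)
        y[2:5, 2:5] = 1
        rep = evaluate(y, y)
        assert rep.accuracy == rep.precision == rep.recall == 1.0
        assert rep.iou == rep.dsc == 1.0

    def test_half_overlap_closed_form(self):
        p = np.zeros((20, 20), dtype=np.uint8)
        g = np.zeros((20, 20), dtype=np.uint8)
        p.ravel()[:100] = 1
        g.ravel()[50:150] = 1
        rep = evaluate(p, g)
        assert np.isclose(rep.iou, 1 / 3)
        assert np.isclose(rep.dsc, 0.5)
        assert np.isclose(rep.precision, 0.5)
        assert np.isclose(rep.recall, 0.5)

    def test_outside_roi_flips_ignored(self, roi128):
        rng = np.random.default_rng(5)
        pred = (rng.random((128, 128)) > 0.5).astype(np.uint8) * roi128
        truth = (rng.random((128, 128)) > 0.5).astype(np.uint8) * roi128
        rep1 = evaluate(pred, truth, roi128)
        corrupted = pred.copy()
        corrupted[roi128 == 0] = 1  # flip every outside pixel
        rep2 = evaluate(corrupted, truth, roi128)
        assert rep1 == rep2

    def test_empty_mask_conventions(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        o = np.zeros((4, 4), dtype=np.uint8)
        o[0, 0] = 1
        both_empty = evaluate(z, z)
        assert both_empty.dsc == both_empty.iou == 1.0
        one_empty = evaluate(o, z)
        assert one_empty.dsc == one_empty.iou == 0.0

    def test_dsc_iou_identity_random_masks(self):
        """DSC = 2 IoU / (1 + IoU) on binary masks."""
        rng = np.random.default_rng(6)
        for _ in range(1000):
            p = (rng.random((6, 6)) > rng.random()).astype(np.uint8)
            g = (rng.random((6, 6)) > rng.random()).astype(np.uint8)
            rep = evaluate(p, g)
            assert np.isclose(rep.dsc, 2 * rep.iou / (1 + rep.iou), atol=1e-12)

    def test_soft_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.full((3, 3), 0.5), np.zeros((3, 3)))
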