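"""Loss closed forms, invariants and gradients."""

import math

import numpy as np
import pytest

from dscanet import autodiff as ad
from dscanet.autodiff import Tensor
from dscanet.losses import (LossWeights, bce_loss, body_loss, dice_loss,
                            edge_loss_total, edge_pixel_loss, total_loss)

from conftest import numeric_gradient


class TestEdgePixelLoss:
    def test_perfect_predictions_vanish(self):
        w = LossWeights()
        gt = np.array([[1.0, 0.0]])
        pred = Tensor(np.array([[1.0 - 1e-9, 1e-9]]))
        assert edge_pixel_loss(pred, gt, w).item() < 1e-5

    def test_ambiguous_band_is_ignored(self):
        w = LossWeights()  # gamma = 0.6
        pred = Tensor(np.array([[0.9]]))
        assert edge_pixel_loss(pred, np.array([[0.3]]), w).item() == 0.0

    def test_hand_computed_values_at_half(self):
        w = LossWeights()  # beta = 0.8, lam = 2.0 → alpha = 0.4
        pred = Tensor(np.array([[0.5]]))
        pos = edge_pixel_loss(pred, np.array([[1.0]]), w).item()
        neg = edge_pixel_loss(pred, np.array([[0.0]]), w).item()
        assert pos == pytest.approx(-0.8 * math.log(0.5), rel=1e-5)   # 0.5545
        assert neg == pytest.approx(-0.4 * math.log(0.5), rel=1e-5)   # 0.2773
        assert pos == pytest.approx(0.55452, abs=1e-4)
        assert neg == pytest.approx(0.27726, abs=1e-4)

    def test_alpha_definition(self):
        w = LossWeights(beta=0.7, lam=3.0)
        assert w.alpha == pytest.approx(3.0 * 0.3)


class TestEdgeLossTotal:
    def test_sum_over_stages_and_additivity(self, rng):
        w = LossWeights()
        gt = (rng.uniform(size=(1, 1, 4, 4)) > 0.5).astype(np.float32)
        maps = [Tensor(rng.uniform(0.1, 0.9, size=(1, 1, 4, 4)).astype(np.float32))
                for _ in range(4)]
        tot, per = edge_loss_total(maps, gt, w)
        assert tot.item() == pytest.approx(sum(p.item() for p in per), rel=1e-6)
        assert len(per) == 4

    def test_tiled_image_doubles_sum_form_loss(self, rng):
        w = LossWeights(edge_reduction="sum")
        gt = (rng.uniform(size=(1, 1, 4, 4)) > 0.5).astype(np.float32)
        pred = rng.uniform(0.1, 0.9, size=(1, 1, 4, 4)).astype(np.float32)
        single = edge_pixel_loss(Tensor(pred), gt, w).item()
        doubled = edge_pixel_loss(Tensor(np.concatenate([pred, pred], axis=3)),
                                  np.concatenate([gt, gt], axis=3), w).item()
        assert doubled == pytest.approx(2 * single, rel=1e-5)

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            edge_loss_total([Tensor(np.zeros((1, 1, 4, 4)) + 0.5)],
                            np.zeros((1, 1, 8, 8)))


class TestBceDice:
    def test_bce_half_is_ln2(self, rng):
        gt = (rng.uniform(size=(3, 3)) > 0.5).astype(np.float32)
        pred = Tensor(np.full((3, 3), 0.5))
        assert bce_loss(pred, gt).item() == pytest.approx(math.log(2), rel=1e-6)

    def test_bce_hand_case(self):
        gt = np.array([1.0, 0.0, 1.0, 0.0])
        pred = Tensor(np.array([0.9, 0.2, 0.8, 0.4]))
        ref = -0.25 * (math.log(0.9) + math.log(0.8) + math.log(0.8) + math.log(0.6))
        assert bce_loss(pred, gt).item() == pytest.approx(ref, rel=1e-6)
        assert bce_loss(pred, gt).item() == pytest.approx(0.26562, abs=2e-4)

    def test_dice_perfect_and_disjoint(self):
        gt = np.zeros((10, 10), dtype=np.float32)
        gt[:5] = 1
        assert dice_loss(Tensor(gt.copy()), gt).item() == pytest.approx(0.0, abs=1e-6)
        assert dice_loss(Tensor(1.0 - gt), gt).item() == pytest.approx(1.0, abs=0.02)

    def test_dice_half_overlap_is_one_third(self):
        gt = np.zeros(300, dtype=np.float32)
        gt[:100] = 1
        pred = np.zeros(300, dtype=np.float32)
        pred[:50] = 1  # half of the positives, no false positives
        # 1 − 2·50/150 = 1/3 (up to the ε smoothing)
        assert dice_loss(Tensor(pred), gt).item() == pytest.approx(1 / 3, abs=5e-3)

    def test_dice_empty_versus_empty_is_zero(self):
        z = np.zeros((4, 4), dtype=np.float32)
        assert dice_loss(Tensor(z.copy()), z).item() == pytest.approx(0.0, abs=1e-7)

    def test_dice_invariant_under_joint_permutation(self, rng):
        gt = (rng.uniform(size=64) > 0.7).astype(np.float32)
        pred = rng.uniform(size=64).astype(np.float32)
        perm = rng.permutation(64)
        a = dice_loss(Tensor(pred.copy()), gt).item()
        b = dice_loss(Tensor(pred[perm]), gt[perm]).item()
        assert a == pytest.approx(b, rel=1e-6)


class TestCombinedLosses:
    def test_body_loss_weighted_combination(self):
        # bce = ln 2 at pred 0.5; build dice = 0.5 via quarter overlap
        w = LossWeights()
        l, b, d = body_loss(Tensor(np.full(4, 0.5)), np.array([1, 0, 1, 0.0]), w)
        assert l.item() == pytest.approx(0.6 * b.item() + 0.4 * d.item(), rel=1e-6)
        w2 = LossWeights(lambda1=1.0, lambda2=0.0)
        l2, b2, _ = body_loss(Tensor(np.full(4, 0.5)), np.array([1, 0, 1, 0.0]), w2)
        assert l2.item() == pytest.approx(b2.item(), rel=1e-6)

    def test_stated_component_values_compose(self):
        w = LossWeights()
        assert 0.6 * 1.0 + 0.4 * 0.5 == pytest.approx(0.8)
        assert 0.8 + w.omega * 2.0 == pytest.approx(1.4)

    def test_total_loss_report_invariants(self, rng):
        w = LossWeights()
        gt = (rng.uniform(size=(1, 1, 6, 6)) > 0.6).astype(np.float32)
        edge_gt = (rng.uniform(size=(1, 1, 6, 6)) > 0.8).astype(np.float32)
        pred = Tensor(rng.uniform(0.05, 0.95, size=(1, 1, 6, 6)))
        maps = [Tensor(rng.uniform(0.05, 0.95, size=(1, 1, 6, 6)))
                for _ in range(4)]
        loss, rep = total_loss(pred, gt, maps, edge_gt, w)
        assert rep.body == pytest.approx(w.lambda1 * rep.bce + w.lambda2 * rep.dice,
                                         rel=1e-4)
        assert rep.total == pytest.approx(rep.body + w.omega * rep.edge, rel=1e-4)
        assert loss.item() == pytest.approx(rep.total, rel=1e-6)
        assert min(rep.bce, rep.dice, rep.edge, rep.total) >= 0

    def test_omega_zero_decouples_edge_branch(self, rng):
        gt = (rng.uniform(size=(1, 1, 4, 4)) > 0.5).astype(np.float32)
        pred = Tensor(rng.uniform(0.2, 0.8, size=(1, 1, 4, 4)))
        maps = [Tensor(rng.uniform(0.2, 0.8, size=(1, 1, 4, 4)))]
        w = LossWeights(omega=0.0)
        loss, rep = total_loss(pred, gt, maps, gt, w)
        assert rep.total == pytest.approx(rep.body, rel=1e-6)

    def test_total_loss_gradient_matches_finite_differences(self, rng):
        w = LossWeights()
        gt = (rng.uniform(size=(1, 1, 3, 3)) > 0.5).astype(np.float64)
        edge_gt = (rng.uniform(size=(1, 1, 3, 3)) > 0.7).astype(np.float64)
        pred = Tensor(rng.uniform(0.2, 0.8, size=(1, 1, 3, 3)), requires_grad=True)
        emap = Tensor(rng.uniform(0.2, 0.8, size=(1, 1, 3, 3)), requires_grad=True)
        loss, _ = total_loss(pred, gt, [emap], edge_gt, w)
        loss.backward()
        for t in (pred, emap):
            ana = t.grad.copy()

            def f():
                with ad.no_grad():
                    pass
                l, _ = total_loss(Tensor(pred.data), gt, [Tensor(emap.data)],
                                  edge_gt, w)
                return l.item()

            num = numeric_gradient(f, t.data, eps=1e-5)
            assert np.abs(ana - num).max() < 1e-4 * (np.abs(num).max() + 1.0)
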