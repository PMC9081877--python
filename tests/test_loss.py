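"""Contour-search loss: balance weights, pointwise piecewise form and
whole-image summation against exhaustive oracles."""

import numpy as np
import pytest

from dewquant import LossConfig, balance_weights, image_loss, pointwise_loss
from dewquant.irrd.loss import loss_gradients_wrt_logits

from _oracles import image_loss_oracle, pointwise_loss_oracle


def toy_4x4():
    """Hand-built 4x4 instance: n_pos=2, n_neg=6, s_plus=3, s_minus=4."""
    consensus = np.array(
        [
            [0.0, 0.25, 1.0, 0.0],
            [0.3, 0.75, 0.4, 0.0],
            [0.0, 0.3, 0.25, 0.0],
            [0.49, 0.3, 0.4, 0.0],
        ]
    )
    label_map = np.zeros((4, 4), dtype=np.int32)
    label_map[0, 0] = 1  # region of area 1
    label_map[2:4, 0] = 2
    label_map[3, 1] = 2  # region of area 3 (largest)
    return consensus, label_map


class TestBalanceWeights:
    def test_hand_arithmetic_example(self):
        consensus, label_map = toy_4x4()
        alpha_w, beta_w, bal = balance_weights(
            consensus, label_map, LossConfig(eta=0.5, lam=1.1)
        )
        assert (bal.n_pos, bal.n_neg) == (2, 6)
        assert (bal.s_plus, bal.s_minus) == (3, 4)
        assert alpha_w == pytest.approx(1.1 * (2 / 8) * (3 / 7))
        assert beta_w == pytest.approx((6 / 8) * (3 / 7))

    def test_single_region_ratio_is_half(self):
        consensus = np.zeros((6, 6))
        consensus[0, 0] = 1.0
        label_map = np.zeros((6, 6), dtype=np.int32)
        label_map[2:5, 2:5] = 1
        _, _, bal = balance_weights(consensus, label_map)
        assert bal.s_plus == bal.s_minus == 9
        ratio = bal.s_plus / (bal.s_plus + bal.s_minus)
        assert ratio == 0.5

    def test_balanced_classes_with_unit_lambda(self):
        consensus = np.zeros((4, 4))
        consensus[:2] = 1.0  # 8 positive, 8 negative
        label_map = np.zeros((4, 4), dtype=np.int32)
        label_map[3, 3] = 1
        alpha_w, beta_w, _ = balance_weights(
            consensus, label_map, LossConfig(eta=0.5, lam=1.0)
        )
        assert alpha_w == pytest.approx(beta_w)

    def test_alpha_linear_in_lambda_beta_independent(self):
        consensus, label_map = toy_4x4()
        a1, b1, _ = balance_weights(consensus, label_map, LossConfig(lam=1.0))
        a2, b2, _ = balance_weights(consensus, label_map, LossConfig(lam=2.0))
        assert a2 == pytest.approx(2 * a1)
        assert b2 == pytest.approx(b1)

    def test_all_controversial_rejected(self):
        consensus = np.full((3, 3), 0.25)
        with pytest.raises(ValueError):
            balance_weights(consensus, np.zeros((3, 3), dtype=np.int32))


class TestPointwiseLoss:
    def test_controversial_pixel_contributes_nothing(self):
        for p in (0.01, 0.5, 0.99):
            assert pointwise_loss(p, 0.3, 1.0, 1.0, eta=0.5) == 0.0

    def test_confident_correct_negative_vanishes(self):
        assert pointwise_loss(1e-7, 0.0, 1.0, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_hand_value_for_uncertain_positive(self):
        assert pointwise_loss(0.5, 1.0, 1.0, 2.0) == pytest.approx(2 * np.log(2))

    def test_nonnegative_everywhere(self, rng):
        p = rng.random(100)
        y = rng.random(100)
        out = pointwise_loss(p, y, 0.7, 1.3)
        assert np.all(out >= 0)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(50):
            p, y = rng.random(), rng.random()
            assert pointwise_loss(p, y, 0.8, 1.2, eta=0.5) == pytest.approx(
                pointwise_loss_oracle(p, y, 0.8, 1.2, 0.5)
            )


class TestImageLoss:
    def test_perfect_prediction_near_zero(self):
        consensus, label_map = toy_4x4()
        perfect = np.where(consensus >= 0.5, 1.0 - 1e-9, 1e-9)
        perfect = np.where((consensus > 0) & (consensus < 0.5), 0.5, perfect)
        out = image_loss([perfect, perfect], perfect, consensus, label_map)
        assert out.per_pixel_mean < 1e-5

    def test_fused_identical_to_single_side_doubles_total(self, rng):
        consensus, label_map = toy_4x4()
        prob = rng.random((4, 4))
        single = image_loss([prob], prob, consensus, label_map)
        assert single.per_map[0] == pytest.approx(single.per_map[1])
        assert single.total == pytest.approx(2 * single.per_map[0])

    @pytest.mark.parametrize("lam,eta", [(1.1, 0.5), (1.0, 0.3), (2.5, 0.8)])
    def test_matches_exhaustive_summation_oracle(self, rng, lam, eta):
        consensus, label_map = toy_4x4()
        cfg = LossConfig(eta=eta, lam=lam)
        alpha_w, beta_w, _ = balance_weights(consensus, label_map, cfg)
        maps = [rng.random((4, 4)) for _ in range(3)]
        ours = image_loss(maps[:-1], maps[-1], consensus, label_map, cfg)
        oracle = image_loss_oracle(maps, consensus, alpha_w, beta_w, eta)
        assert ours.total == pytest.approx(oracle)

    def test_oracle_equivalence_on_larger_maps(self, rng):
        consensus = (rng.random((8, 8)) < 0.25).astype(float) * rng.random((8, 8))
        consensus = np.round(consensus * 4) / 4
        label_map = np.zeros((8, 8), dtype=np.int32)
        label_map[1:4, 1:4] = 1
        label_map[5:8, 5:7] = 2
        cfg = LossConfig()
        alpha_w, beta_w, _ = balance_weights(consensus, label_map, cfg)
        maps = [rng.random((8, 8)) for _ in range(4)]
        ours = image_loss(maps[:-1], maps[-1], consensus, label_map, cfg)
        assert ours.total == pytest.approx(
            image_loss_oracle(maps, consensus, alpha_w, beta_w, cfg.eta)
        )


class TestLossGradients:
    def test_closed_form_gradient_matches_finite_difference(self, rng):
        consensus, _ = toy_4x4()
        z = rng.standard_normal((4, 4))
        aw, bw, eta = 0.6, 1.4, 0.5
        total, (grad,) = loss_gradients_wrt_logits([z], consensus, aw, bw, eta)
        eps = 1e-6
        for i in range(4):
            for j in range(4):
                zp = z.copy()
                zp[i, j] += eps
                tp, _ = loss_gradients_wrt_logits([zp], consensus, aw, bw, eta)
                zm = z.copy()
                zm[i, j] -= eps
                tm, _ = loss_gradients_wrt_logits([zm], consensus, aw, bw, eta)
                assert grad[i, j] == pytest.approx((tp - tm) / (2 * eps), abs=1e-5)

    def test_controversial_pixels_have_zero_gradient(self, rng):
        consensus, _ = toy_4x4()
        z = rng.standard_normal((4, 4))
        _, (grad,) = loss_gradients_wrt_logits([z], consensus, 1.0, 1.0, 0.5)
        controversial = (consensus > 0) & (consensus < 0.5)
        assert np.all(grad[controversial] == 0)
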