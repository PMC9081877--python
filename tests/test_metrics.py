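"""Region- and edge-level evaluation metrics against hand arithmetic and
brute-force matching oracles."""

import numpy as np
import pytest

from dewquant import (
    ap_dew_area,
    ap_edge,
    area_error_report,
    match_edge_pixels,
    ods_ois,
    pr_at_threshold,
)

from _oracles import max_matching_oracle


class TestApDewArea:
    def test_perfect_detection(self):
        assert ap_dew_area([100, 200], [100, 200]) == 1.0

    def test_hand_arithmetic(self):
        assert ap_dew_area([100, 200], [90, 180]) == pytest.approx(0.9)

    def test_total_miss(self):
        assert ap_dew_area([100], [0]) == 0.0

    def test_overshoot_clamped_not_rewarded(self):
        # detecting 3x the annotated area must not score above zero,
        # let alone above one
        assert ap_dew_area([100], [300]) == 0.0
        assert ap_dew_area([100], [110]) == pytest.approx(0.9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ap_dew_area([], [])

    def test_monotone_in_single_error(self):
        values = [ap_dew_area([100, 100], [100, 100 + d]) for d in (0, 10, 30, 60)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestMatchEdgePixels:
    def test_identical_masks(self, rng):
        mask = (rng.random((12, 12)) < 0.2).astype(np.uint8)
        tp, n_pred, n_gt = match_edge_pixels(mask, mask, tol_px=1.0)
        assert tp == n_pred == n_gt == mask.sum()

    def test_shift_beyond_tolerance(self):
        gt = np.zeros((10, 10), dtype=np.uint8)
        gt[5, :] = 1
        pred = np.zeros_like(gt)
        pred[2, :] = 1  # 3 px away
        tp, _, _ = match_edge_pixels(pred, gt, tol_px=2.0)
        assert tp == 0

    def test_matches_optimal_bipartite_oracle(self, rng):
        for _ in range(10):
            pred = (rng.random((10, 10)) < 0.25).astype(np.uint8)
            gt = (rng.random((10, 10)) < 0.25).astype(np.uint8)
            ours = match_edge_pixels(pred, gt, tol_px=1.5)
            oracle = max_matching_oracle(pred, gt, tol_px=1.5)
            assert ours == oracle


class TestPrAndCurves:
    def test_perfect_prediction_gives_unit_f(self, glass_scene):
        _, gt = glass_scene
        prob = (gt.consensus_edges >= 0.5).astype(np.float64)
        for t in (0.25, 0.5, 0.9):
            p, r, f = pr_at_threshold(prob, gt.consensus_edges, t)
            assert f == 1.0

    def test_empty_prediction_zero_recall(self, glass_scene):
        _, gt = glass_scene
        p, r, f = pr_at_threshold(
            np.zeros_like(gt.consensus_edges), gt.consensus_edges, 0.5
        )
        assert r == 0.0 and f == 0.0

    def test_small_instance_matches_direct_formula(self, rng):
        prob = rng.random((12, 12))
        cons = (rng.random((12, 12)) < 0.2).astype(np.float64)
        t = 0.6
        tp, n_pred, n_gt = max_matching_oracle(prob >= t, cons >= 0.5, 2.0)
        precision = tp / n_pred if n_pred else 1.0
        recall = tp / n_gt if n_gt else 1.0
        expect_f = (
            0.0
            if precision + recall == 0
            else 2 * precision * recall / (precision + recall)
        )
        p, r, f = pr_at_threshold(prob, cons, t, eta=0.5, tol_px=2.0)
        assert (p, r, f) == pytest.approx((precision, recall, expect_f))

    def test_controversial_pixels_do_not_count_as_false_positives(self):
        cons = np.zeros((8, 8))
        cons[4, 4] = 0.25  # controversial under eta=0.5
        cons[2, 2] = 1.0
        prob = np.zeros((8, 8))
        prob[4, 4] = 1.0
        prob[2, 2] = 1.0
        p, r, f = pr_at_threshold(prob, cons, 0.5, eta=0.5, tol_px=0.5)
        assert p == 1.0 and r == 1.0

    def test_ap_edge_perfect_and_empty(self, glass_scene):
        _, gt = glass_scene
        perfect = (gt.consensus_edges >= 0.5).astype(np.float64)
        assert ap_edge(perfect, gt.consensus_edges) == pytest.approx(1.0)
        assert ap_edge(np.zeros_like(perfect), gt.consensus_edges) == pytest.approx(
            0.0
        )

    def test_ap_edge_matches_hand_integrated_trapezoid(self, rng):
        prob = rng.random((12, 12))
        cons = (rng.random((12, 12)) < 0.2).astype(np.float64)
        grid = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        points = []
        for t in grid:
            tp, n_pred, n_gt = max_matching_oracle(prob >= t, cons >= 0.5, 2.0)
            precision = tp / n_pred if n_pred else 1.0
            recall = tp / n_gt if n_gt else 1.0
            points.append((recall, precision))
        points.sort()
        rec = [0.0] + [p[0] for p in points]
        pre = [points[0][1]] + [p[1] for p in points]
        expected = np.trapezoid(pre, rec)
        got = ap_edge(prob, cons, eta=0.5, tol_px=2.0, thresholds=grid)
        assert got == pytest.approx(expected)


class TestOdsOis:
    def _random_instance(self, rng, quality=2.0):
        cons = np.zeros((24, 24))
        cons[rng.integers(4, 20), 4:20] = 1.0
        noise = rng.random((24, 24))
        prob = np.clip(cons * rng.uniform(0.5, 1.0) + 0.3 * noise, 0, 1)
        return prob, cons

    def test_single_image_ods_equals_ois(self, rng):
        dataset = [self._random_instance(rng)]
        ods, ois = ods_ois(dataset, tol_px=2.0)
        assert ods == pytest.approx(ois)

    def test_perfect_predictions(self, glass_scene):
        _, gt = glass_scene
        prob = (gt.consensus_edges >= 0.5).astype(np.float64)
        ods, ois = ods_ois([(prob, gt.consensus_edges)] * 3)
        assert ods == 1.0 and ois == 1.0

    def test_ois_dominates_ods(self, rng):
        for _ in range(5):
            dataset = [self._random_instance(rng) for _ in range(4)]
            ods, ois = ods_ois(dataset, tol_px=2.0)
            assert ois >= ods - 1e-12

    def test_order_invariance(self, rng):
        dataset = [self._random_instance(rng) for _ in range(3)]
        a = ods_ois(dataset, tol_px=2.0)
        b = ods_ois(dataset[::-1], tol_px=2.0)
        assert a == pytest.approx(b)


class TestAreaErrorReport:
    def test_perfect_detection_zero_errors(self):
        report, _ = area_error_report([(100, 100), (50, 50)])
        assert report["error"].tolist() == [0, 0]
        assert report["accuracy"].tolist() == [1.0, 1.0]

    def test_hand_arithmetic(self):
        report, _ = area_error_report([(100, 140)])
        assert report["error"].iloc[0] == 40
        assert report["accuracy"].iloc[0] == pytest.approx(0.6)

    def test_row_per_ground_truth_droplet(self, rng):
        pairs = [(int(a), int(a * rng.uniform(0.5, 1.5))) for a in
                 rng.integers(50, 500, size=7)]
        report, curve = area_error_report(pairs)
        assert len(report) == 7
        assert curve["n"].sum() == 7
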