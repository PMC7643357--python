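"""Loss re-weighting by detected inter-SSE contacts; range-banded top-k."""

import numpy as np
import pytest

import ssedetect as sd
from ssedetect.application import (
    MIN_SEPARATION,
    range_of,
    reweighted_cross_entropy,
    topk_accuracy,
    weight_map_from_detections,
)


def _det(region, ctype="HH", score=0.8):
    return sd.Detection(region=sd.RectRegion(*region), type=ctype, score=score)


class TestWeightMap:
    def test_no_detections_gives_all_ones(self):
        assert np.array_equal(weight_map_from_detections([], 12).W, np.ones((12, 12)))

    def test_single_detection_sets_one_plus_score(self):
        w = weight_map_from_detections([_det((10, 20, 40, 50), score=0.80)], 60).W
        assert np.all(w[10:20, 40:50] == pytest.approx(1.8))
        assert np.all(w[40:50, 10:20] == pytest.approx(1.8))
        inside = np.zeros((60, 60), bool)
        inside[10:20, 40:50] = inside[40:50, 10:20] = True
        assert np.all(w[~inside] == 1.0)

    def test_two_disjoint_detections(self):
        w = weight_map_from_detections(
            [_det((0, 5, 20, 25), score=0.7), _det((30, 35, 50, 55), score=0.9)], 60
        ).W
        assert np.all(w[0:5, 20:25] == pytest.approx(1.7))
        assert np.all(w[30:35, 50:55] == pytest.approx(1.9))

    def test_overlapping_detections_rejected(self):
        with pytest.raises(ValueError):
            weight_map_from_detections(
                [_det((0, 5, 20, 25)), _det((3, 8, 22, 27))], 40
            )


class TestReweightedLoss:
    def test_all_ones_weights_equal_plain_loss(self):
        rng = np.random.default_rng(0)
        L = 30
        pred = (lambda m: (m + m.T) / 2)(rng.random((L, L)))
        truth = (rng.random((L, L)) > 0.8).astype(float)
        truth = np.triu(truth, 1) + np.triu(truth, 1).T
        plain = reweighted_cross_entropy(pred, truth, None)
        ones = reweighted_cross_entropy(pred, truth, np.ones((L, L)))
        assert ones == pytest.approx(plain, abs=1e-10)

    def test_single_pair_hand_arithmetic(self):
        L = 10
        pred = np.zeros((L, L))
        truth = np.zeros((L, L))
        pred[0, 9] = pred[9, 0] = 0.5
        truth[0, 9] = truth[9, 0] = 1.0
        W = np.ones((L, L))
        W[0, 9] = W[9, 0] = 1.8
        # the (0, 9) pair contributes 1.8 * ln 2; all other pairs are
        # correct zero predictions contributing only the 1e-7 clamp
        val = reweighted_cross_entropy(pred, truth, W)
        assert val == pytest.approx(1.8 * np.log(2), rel=1e-4)

    def test_perfect_prediction_loss_vanishes_within_clamp(self):
        L = 20
        truth = np.zeros((L, L))
        truth[2, 12] = truth[12, 2] = 1.0
        loss = reweighted_cross_entropy(truth, truth, None)
        assert loss == pytest.approx(0.0, abs=1e-4)

    def test_loss_monotone_in_any_single_weight(self):
        rng = np.random.default_rng(1)
        L = 25
        pred = np.clip((lambda m: (m + m.T) / 2)(rng.random((L, L))), 0.05, 0.95)
        truth = (np.triu(rng.random((L, L)) > 0.7, 1)).astype(float)
        truth = truth + truth.T
        W = np.ones((L, L))
        base = reweighted_cross_entropy(pred, truth, W)
        for (i, j) in [(0, 10), (3, 20), (5, 24)]:
            W2 = W.copy()
            W2[i, j] = W2[j, i] = 2.5
            assert reweighted_cross_entropy(pred, truth, W2) >= base

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            reweighted_cross_entropy(np.zeros((4, 4)), np.zeros((5, 5)), None)


class TestRangeBands:
    @pytest.mark.parametrize(
        "sep,band",
        [(5, "none"), (6, "short"), (11, "short"), (12, "medium"),
         (23, "medium"), (24, "long"), (80, "long")],
    )
    def test_band_boundaries(self, sep, band):
        assert range_of(0, sep) == band
        assert range_of(sep, 0) == band

    def test_same_residue_is_an_error(self):
        with pytest.raises(ValueError):
            range_of(4, 4)

    def test_minimum_separation_matches_short_band_start(self):
        assert MIN_SEPARATION == 6


def topk_oracle(pred, truth, band, divisor):
    """Brute-force ranking over explicitly enumerated band pairs."""
    from ssedetect.application import RANGE_BANDS

    L = pred.shape[0]
    lo, hi = RANGE_BANDS[band]
    pairs = [
        (i, j) for i in range(L) for j in range(i + 1, L) if lo <= j - i <= hi
    ]
    k = L // divisor
    if k < 1 or not pairs:
        return None
    ranked = sorted(pairs, key=lambda p: (-pred[p], p[0], p[1]))[:k]
    return sum(1 for p in ranked if truth[p] > 0) / k


class TestTopK:
    def test_perfect_predictor_with_enough_contacts(self):
        L = 40
        truth = np.zeros((L, L))
        for (i, j) in [(0, 30), (1, 33), (2, 36), (3, 39), (5, 35)]:
            truth[i, j] = truth[j, i] = 1.0
        acc = topk_accuracy(truth, truth, "long", 10)  # k = 4
        assert acc == 1.0

    def test_fewer_true_contacts_than_k(self):
        L = 40
        truth = np.zeros((L, L))
        truth[0, 30] = truth[30, 0] = 1.0
        pred = truth * 0.9
        acc = topk_accuracy(pred, truth, "long", 10)  # k = 4, t = 1
        assert acc == pytest.approx(1 / 4)

    def test_empty_band_returns_missing(self):
        L = 20  # no pairs with separation >= 24
        assert topk_accuracy(np.zeros((L, L)), np.zeros((L, L)), "long", 10) is None

    def test_matches_brute_force_oracle_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            L = int(rng.integers(12, 50))
            pred = (lambda m: (m + m.T) / 2)(rng.random((L, L)))
            truth = np.triu((rng.random((L, L)) > 0.8), 1).astype(float)
            truth = truth + truth.T
            for band in ("short", "medium", "long"):
                for divisor in (10, 5, 2, 1):
                    got = topk_accuracy(pred, truth, band, divisor)
                    expect = topk_oracle(pred, truth, band, divisor)
                    if expect is None:
                        assert got is None
                    else:
                        assert got == pytest.approx(expect)
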