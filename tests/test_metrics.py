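import numpy as np
import pytest

from aswnet.errors import InsufficientPairs, ShapeError
from aswnet.io import InstanceMask
from aswnet.metrics import (aji, area_correlation, dice1, dice2, evaluate,
                            mean_report, nucleus_areas, panoptic_quality)
from oracles import (oracle_aji, oracle_dice1, oracle_dice2, oracle_pq,
                     random_mask)


def masks(pred, truth):
    return InstanceMask(np.asarray(pred, np.int32)), InstanceMask(np.asarray(truth, np.int32))


class TestDice1:
    def test_identity_is_one(self, small_sample):
        m = small_sample.truth
        assert dice1(m, m) == 1.0

    def test_disjoint_is_zero(self):
        p, t = masks([[1, 0], [0, 0]], [[0, 0], [0, 1]])
        assert dice1(p, t) == 0.0

    def test_shifted_square_is_half(self, shifted_square_pair):
        pred, truth = shifted_square_pair
        assert dice1(pred, truth) == 0.5

    def test_symmetry(self, rng):
        p, t = masks(random_mask(rng, 16), random_mask(rng, 16))
        assert dice1(p, t) == dice1(t, p)


class TestDice2:
    def test_identity_and_empty_cases(self, small_sample):
        m = small_sample.truth
        assert dice2(m, m) == 1.0
        empty = InstanceMask(np.zeros(m.shape, np.int32))
        assert dice2(empty, m) == 0.0
        assert dice2(empty, empty) == 1.0

    def test_single_object_reduces_to_dice1(self, shifted_square_pair):
        pred, truth = shifted_square_pair
        assert dice2(pred, truth) == dice1(pred, truth) == 0.5


class TestAji:
    def test_identity_is_one(self, small_sample):
        assert aji(small_sample.truth, small_sample.truth) == 1.0

    def test_shifted_square_is_one_third(self, shifted_square_pair):
        pred, truth = shifted_square_pair
        assert aji(pred, truth) == pytest.approx(2 / 6, abs=1e-12)

    def test_unused_prediction_penalizes_union(self):
        truth = np.zeros((8, 8), np.int32)
        truth[1:3, 1:3] = 1
        pred = truth.copy()
        pred[5:7, 5:7] = 2  # spurious object, size 4
        p, t = masks(pred, truth)
        assert aji(p, t) == pytest.approx(4 / (4 + 4))


class TestPanopticQuality:
    def test_identity_all_ones(self, small_sample):
        m = small_sample.truth
        dq, sq, pq, table = panoptic_quality(m, m)
        assert (dq, sq, pq) == (1.0, 1.0, 1.0)
        assert len(table.pairs) == m.n_instances

    def test_low_iou_gives_zero(self, shifted_square_pair):
        pred, truth = shifted_square_pair
        dq, sq, pq, table = panoptic_quality(pred, truth)
        assert dq == 0.0 and pq == 0.0
        assert table.unmatched_gt == [1] and table.unmatched_pred == [1]

    def test_one_match_one_spurious(self):
        truth = np.zeros((8, 8), np.int32)
        truth[1:4, 1:4] = 1
        pred = truth.copy()
        pred[6:8, 6:8] = 5
        dq, sq, pq, _ = panoptic_quality(*masks(pred, truth))
        assert dq == pytest.approx(1 / 1.5)
        assert sq == 1.0
        assert pq == pytest.approx(2 / 3)


def test_evaluate_composes_individual_metrics(shifted_square_pair):
    pred, truth = shifted_square_pair
    rep = evaluate(pred, truth)
    assert rep.dice1 == dice1(pred, truth)
    assert rep.dice2 == dice2(pred, truth)
    assert rep.aji == aji(pred, truth)
    dq, sq, pq, _ = panoptic_quality(pred, truth)
    assert (rep.dq, rep.sq, rep.pq) == (dq, sq, pq)
    assert rep.pq == pytest.approx(rep.dq * rep.sq, abs=1e-9)
    assert (rep.tp, rep.fp, rep.fn) == (0, 1, 1)


def test_empty_pred_vs_truth_all_zero(small_sample):
    truth = small_sample.truth
    empty = InstanceMask(np.zeros(truth.shape, np.int32))
    rep = evaluate(empty, truth)
    assert rep.dice1 == rep.dice2 == rep.aji == rep.pq == 0.0


def test_shape_mismatch_raises():
    p = InstanceMask(np.zeros((4, 4), np.int32))
    t = InstanceMask(np.zeros((5, 5), np.int32))
    for fn in (dice1, dice2, aji):
        with pytest.raises(ShapeError):
            fn(p, t)


@pytest.mark.parametrize("seed", range(5))
def test_label_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    pred = random_mask(rng, 24, 4)
    truth = random_mask(rng, 24, 4)
    perm = rng.permutation(100) + 1
    pred_perm = np.where(pred > 0, perm[pred], 0)
    r1 = evaluate(*masks(pred, truth))
    r2 = evaluate(*masks(pred_perm, truth))
    for attr in ("dice1", "dice2", "aji", "dq", "sq", "pq"):
        assert getattr(r1, attr) == pytest.approx(getattr(r2, attr), abs=1e-12)


def test_oracle_agreement_on_random_masks(rng):
    """Spot agreement with the set-based oracles (full sweep in acceptance)."""
    for _ in range(50):
        pred = random_mask(rng, 24, 4)
        truth = random_mask(rng, 24, 4)
        p, t = masks(pred, truth)
        assert dice1(p, t) == pytest.approx(oracle_dice1(pred, truth), abs=1e-12)
        assert dice2(p, t) == pytest.approx(oracle_dice2(pred, truth), abs=1e-12)
        assert aji(p, t) == pytest.approx(oracle_aji(pred, truth), abs=1e-12)
        dq, sq, pq, _ = panoptic_quality(p, t)
        odq, osq, opq, *_ = oracle_pq(pred, truth)
        assert (dq, sq, pq) == pytest.approx((odq, osq, opq), abs=1e-12)


def test_aji_not_above_dice1(rng):
    """Aggregated Jaccard never exceeds pixel Dice (Jaccard <= Dice)."""
    for _ in range(200):
        p, t = masks(random_mask(rng, 20, 4), random_mask(rng, 20, 4))
        assert aji(p, t) <= dice1(p, t) + 1e-12


class TestAreas:
    def test_single_object_area(self):
        m = np.zeros((8, 8), np.int32)
        m[2:6, 2:6] = 1
        assert nucleus_areas(InstanceMask(m)) == [(1, 16)]
        assert nucleus_areas(InstanceMask(np.zeros((4, 4), np.int32))) == []

    def test_areas_conserve_foreground(self, rng):
        m = random_mask(rng, 32, 5)
        total = sum(a for _, a in nucleus_areas(InstanceMask(m)))
        assert total == int((m > 0).sum())

    def test_correlation_identity_and_scaling(self, small_sample):
        truth = small_sample.truth
        r, detail = area_correlation(truth, truth)
        assert r == pytest.approx(1.0)
        assert detail["unmatched_gt"] == []

    def test_correlation_matches_formula_oracle(self):
        truth = np.zeros((40, 40), np.int32)
        pred = np.zeros((40, 40), np.int32)
        sizes = [3, 4, 5, 6, 7]
        for i, s in enumerate(sizes):
            r0 = i * 8
            truth[r0:r0 + s, 0:s] = i + 1
            pred[r0:r0 + s, 0:s - 1] = i + 1  # pred area s*(s-1)
        r, _ = area_correlation(*masks(pred, truth))
        ga = np.array([s * s for s in sizes], float)
        pa = np.array([s * (s - 1) for s in sizes], float)
        expected = (np.mean(ga * pa) - ga.mean() * pa.mean()) / (ga.std() * pa.std())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_raises(self):
        m = np.zeros((8, 8), np.int32)
        m[0:2, 0:2] = 1
        with pytest.raises(InsufficientPairs):
            area_correlation(InstanceMask(m), InstanceMask(m))


def test_mean_report_averages(shifted_square_pair, small_sample):
    r1 = evaluate(*shifted_square_pair)
    r2 = evaluate(small_sample.truth, small_sample.truth)
    mean = mean_report([r1, r2])
    assert mean.aji == pytest.approx((r1.aji + r2.aji) / 2)
    assert mean.tp == r1.tp + r2.tp
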