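"""Metric formulas: segmentation scores, confusion, Brier, AUC, PAM."""

import numpy as np
import pytest

import sdetnet as sd
from sdetnet.metrics import PAM_NORMALIZER, pam


def _vol(voxels, shape=(8, 8, 8)):
    m = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        m[v] = 1
    return m


class TestSegMetrics:
    def test_perfect_agreement(self):
        m = _vol([(1, 1, 1), (2, 2, 2)])
        s = sd.seg_metrics(m, m)
        assert (s.ji, s.f1, s.pr, s.rc) == (1.0, 1.0, 1.0, 1.0)

    def test_partial_overlap_counts(self):
        gt = _vol([(0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 0, 3)])
        pred = _vol([(0, 0, 2), (0, 0, 3), (0, 0, 4), (0, 0, 5)])
        s = sd.seg_metrics(gt, pred)
        assert s.pr == 0.5 and s.rc == 0.5
        assert s.ji == pytest.approx(2 / 6)
        assert s.f1 == 0.5

    def test_empty_prediction_nonempty_truth(self):
        s = sd.seg_metrics(_vol([(0, 0, 0)]), _vol([]))
        assert (s.ji, s.f1, s.pr, s.rc) == (0.0, 0.0, 0.0, 0.0)

    def test_empty_empty_is_flagged_perfect(self):
        s = sd.seg_metrics(_vol([]), _vol([]))
        assert s.degenerate and s.f1 == 1.0

    def test_f1_is_harmonic_mean_of_pr_rc(self, rng):
        for _ in range(20):
            gt = (rng.random((6, 6, 6)) > 0.6).astype(np.uint8)
            pred = (rng.random((6, 6, 6)) > 0.6).astype(np.uint8)
            s = sd.seg_metrics(gt, pred)
            if s.pr + s.rc > 0:
                assert s.f1 == pytest.approx(2 * s.pr * s.rc / (s.pr + s.rc))


class TestConfusion:
    def test_clean_split(self):
        c = sd.confusion_from_probs([1, 1, 0, 0], [0.9, 0.6, 0.4, 0.1])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_boundary_half_is_called_male(self):
        c = sd.confusion_from_probs([0], [0.5])
        assert c.fp == 1

    def test_all_missed(self):
        c = sd.confusion_from_probs([1, 1, 1], [0.0, 0.0, 0.0])
        assert c.fn == 3


class TestBrier:
    def test_perfect(self):
        assert sd.brier([1, 0], [1.0, 0.0]) == 0.0

    def test_worked_example(self):
        assert sd.brier([1, 1, 0, 0], [0.9, 0.6, 0.4, 0.1]) == pytest.approx(
            0.085)

    def test_uninformative_half(self):
        assert sd.brier([1, 0, 1], [0.5, 0.5, 0.5]) == 0.25


def _auc_pairwise(labels, probs):
    """O(n^2) pair-counting oracle: P(score_pos > score_neg) + ties/2."""
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert sd.auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_perfectly_wrong(self):
        assert sd.auc([1, 0], [0.1, 0.9]) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sd.auc([1, 1], [0.2, 0.4])

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        for i in range(50):
            n = int(rng.integers(10, 501))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # discretized probabilities force plenty of ties
            probs = np.round(rng.random(n), 2)
            assert sd.auc(labels, probs) == pytest.approx(
                _auc_pairwise(labels, probs), abs=1e-12)


class TestPAM:
    def test_unit_hexagon_normalizes_to_one(self):
        assert pam(1, 1, 1, 1, 1, 1) == pytest.approx(1.0, abs=1e-4)
        # the normalizer is the printed constant for the unit hexagon area
        assert PAM_NORMALIZER == pytest.approx(3 * np.sqrt(3) / 2, abs=1e-5)

    @pytest.mark.parametrize("r", [0.0, 0.25, 0.5, 0.9])
    def test_uniform_radii_give_r_squared(self, r):
        assert pam(r, r, r, r, r, r) == pytest.approx(r ** 2, abs=1e-4)

    def test_adjacent_zero_pair_contributes_nothing(self):
        # zeroing two opposite axes removes exactly their four triangles
        assert pam(1, 0, 1, 1, 0, 1) == pytest.approx(
            (2 * 0.5 * np.sin(np.pi / 3)) / PAM_NORMALIZER)

    def test_monotone_in_each_argument(self, rng):
        for _ in range(20):
            v = rng.random(6)
            base = pam(*v)
            for i in range(6):
                w = v.copy()
                w[i] = min(1.0, w[i] + 0.1)
                assert pam(*w) >= base - 1e-12

    def test_order_sensitivity_is_real(self):
        v = [1.0, 0.2, 1.0, 0.2, 1.0, 0.2]
        w = [1.0, 1.0, 1.0, 0.2, 0.2, 0.2]
        assert pam(*v) != pytest.approx(pam(*w))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pam(1.2, 1, 1, 1, 1, 1)


class TestClassifierReport:
    def test_balanced_sen_spe_combine_to_acc(self):
        """SEN 0.88 / SPE 0.96 on a balanced 50/50 split give ACC 0.92."""
        labels = np.array([1] * 50 + [0] * 50)
        probs = np.concatenate([
            np.full(44, 0.9), np.full(6, 0.1),   # males: 44 hits, 6 misses
            np.full(48, 0.1), np.full(2, 0.9),   # females: 48 hits, 2 misses
        ])
        r = sd.evaluate_classifier(labels, probs)
        assert r.sen == pytest.approx(0.88)
        assert r.spe == pytest.approx(0.96)
        assert r.acc == pytest.approx(0.92)
        assert r.counts.tp == 44 and r.counts.tn == 48

    def test_composed_worked_example(self):
        r = sd.evaluate_classifier([1, 1, 0, 0], [0.9, 0.6, 0.4, 0.1])
        assert r.acc == 1.0 and r.auc == 1.0
        assert r.br == pytest.approx(0.085)
        assert r.pam == pytest.approx(1.0, abs=1e-4)

    def test_total_failure(self):
        r = sd.evaluate_classifier([1, 0], [0.1, 0.9])
        assert r.acc == 0.0 and r.pam == 0.0

    def test_acc_identity_with_class_sizes(self, rng):
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        probs = rng.random(60)
        r = sd.evaluate_classifier(labels, probs)
        p, n = (labels == 1).sum(), (labels == 0).sum()
        assert r.acc == pytest.approx((r.sen * p + r.spe * n) / (p + n))
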