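"""Evaluation metrics: formula oracles, curve sweeps against rank statistics
and scikit-learn, summaries, paired test, and overlay consistency."""

import numpy as np
import pytest

import isvseg.evaluation as ev


class TestBinarize:
    def test_dominant_isv_channel(self):
        probs = np.stack([np.full((4, 4), 0.9), np.full((4, 4), 0.1)])
        assert ev.binarize(probs).sum() == 16

    def test_tie_goes_to_background(self):
        probs = np.full((2, 4, 4), 0.5)
        assert ev.binarize(probs).sum() == 0

    def test_matches_per_pixel_comparison(self, rng):
        probs = rng.random((2, 6, 6))
        out = ev.binarize(probs)
        for r in range(6):
            for c in range(6):
                assert out[r, c] == (1 if probs[0, r, c] > probs[1, r, c] else 0)


class TestConfusionCounts:
    def test_perfect_and_complement(self, rng):
        gt = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        perfect = ev.confusion_counts(gt, gt)
        assert perfect.FP == perfect.FN == 0
        inverted = ev.confusion_counts(1 - gt, gt)
        assert inverted.TP == inverted.TN == 0

    def test_matches_hand_tally(self, rng):
        pred = (rng.random((4, 4)) > 0.5).astype(np.uint8)
        gt = (rng.random((4, 4)) > 0.5).astype(np.uint8)
        c = ev.confusion_counts(pred, gt)
        tp = fp = tn = fn = 0
        for r in range(4):
            for cc in range(4):
                if pred[r, cc] and gt[r, cc]:
                    tp += 1
                elif pred[r, cc] and not gt[r, cc]:
                    fp += 1
                elif not pred[r, cc] and gt[r, cc]:
                    fn += 1
                else:
                    tn += 1
        assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)
        assert c.total == 16

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ev.confusion_counts(np.zeros((4, 4)), np.zeros((5, 5)))


class TestAccuracyAndDice:
    def test_printed_formula_example(self):
        c = ev.ConfusionCounts(TP=8, TN=4, FP=2, FN=2)
        assert ev.pixel_accuracy(c) == pytest.approx(75.0)
        assert ev.dice(c) == pytest.approx(0.8)

    def test_perfect_prediction(self):
        c = ev.ConfusionCounts(TP=10, TN=6, FP=0, FN=0)
        assert ev.pixel_accuracy(c) == 100.0
        assert ev.dice(c) == 1.0

    def test_no_overlap_dice_zero(self):
        assert ev.dice(ev.ConfusionCounts(TP=0, TN=0, FP=3, FN=5)) == 0.0

    def test_empty_vs_empty_dice_defined_as_one(self):
        assert ev.dice(ev.ConfusionCounts(TP=0, TN=16, FP=0, FN=0)) == 1.0

    def test_two_path_equivalence(self, rng):
        """Metrics via confusion counts equal metrics computed directly
        from the masks."""
        pred = (rng.random((10, 10)) > 0.4).astype(np.uint8)
        gt = (rng.random((10, 10)) > 0.6).astype(np.uint8)
        c = ev.confusion_counts(pred, gt)
        direct_acc = 100.0 * (pred == gt).mean()
        inter = (pred & gt).sum()
        direct_dice = 2 * inter / (pred.sum() + gt.sum())
        assert ev.pixel_accuracy(c) == pytest.approx(direct_acc)
        assert ev.dice(c) == pytest.approx(direct_dice)


class TestCurves:
    def test_perfect_scorer_auc_one(self):
        gt = np.array([0, 0, 1, 1, 0, 1], dtype=np.uint8)
        fpr, tpr, dropped = ev.roc_curve(gt.astype(float), gt)
        assert dropped == 0
        assert ev.auc(fpr, tpr) == pytest.approx(1.0)

    def test_noise_scores_auc_near_half(self):
        rng = np.random.default_rng(99)
        n = 20_000
        gt = (rng.random(n) > 0.5).astype(np.uint8)
        scores = rng.random(n)
        fpr, tpr, _ = ev.roc_curve(scores, gt)
        # AUC of independent scores: mean 0.5, sigma ~ sqrt(1/12) * sqrt(1/n+ + 1/n-)
        n1, n0 = gt.sum(), (1 - gt).sum()
        sigma = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(ev.auc(fpr, tpr) - 0.5) <= 3 * sigma

    def test_auc_equals_mann_whitney_on_toy(self):
        """Eight-pixel toy: trapezoidal ROC area equals the rank-statistic
        U / (n1 * n0)."""
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9, 0.5, 0.2])
        gt = np.array([0, 0, 1, 1, 0, 1, 1, 0], dtype=np.uint8)
        fpr, tpr, _ = ev.roc_curve(scores, gt)
        got = ev.auc(fpr, tpr)
        pos = scores[gt == 1]
        neg = scores[gt == 0]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert got == pytest.approx(u / (len(pos) * len(neg)))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        gt = (rng.random(500) > 0.7).astype(np.uint8)
        scores = np.clip(rng.random(500) * 0.5 + gt * 0.3, 0, 1)
        a1 = ev.auc(*ev.roc_curve(scores, gt)[:2])
        a2 = ev.auc(*ev.roc_curve(scores ** 3, gt)[:2])
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(17)
        gt = (rng.random(800) > 0.6).astype(np.uint8)
        scores = np.clip(0.3 * rng.standard_normal(800) + 0.4 * gt + 0.3, 0, 1)
        ours = ev.auc(*ev.roc_curve(scores, gt)[:2])
        assert ours == pytest.approx(roc_auc_score(gt, scores), abs=1e-9)

    def test_pr_curve_drops_undefined_points(self):
        gt = np.array([1, 1, 0, 0], dtype=np.uint8)
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        precision, recall, dropped = ev.pr_curve(scores, gt)
        assert dropped > 0  # thresholds above every score predict nothing
        assert np.all((precision >= 0) & (precision <= 1))
        assert np.all((recall >= 0) & (recall <= 1))

    def test_degenerate_gt_flagged(self):
        gt = np.ones(10, dtype=np.uint8)
        fpr, tpr, dropped = ev.roc_curve(np.linspace(0, 1, 10), gt)
        assert fpr.size == 0 and dropped > 0

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_curve(np.zeros(4), np.array([0, 1, 0, 1]),
                         thresholds=[0.5, 0.2])


class TestSummarize:
    def test_single_value(self):
        s = ev.summarize([88.0])
        assert s.median == s.mean == 88.0 and s.std == 0.0 and s.n == 1

    def test_two_values(self):
        s = ev.summarize([80.0, 90.0])
        assert s.mean == 85.0 and s.median == 85.0

    def test_matches_textbook_formulas(self, rng):
        v = rng.normal(85, 5, 100)
        s = ev.summarize(v)
        assert s.mean == pytest.approx(v.sum() / 100)
        assert s.std == pytest.approx(
            np.sqrt(((v - v.mean()) ** 2).sum() / 99))
        assert s.median == pytest.approx(np.sort(v)[49:51].mean())


class TestPairedTTest:
    def test_identical_samples_not_significant(self):
        r = ev.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p == 1.0 and not r.significant and r.degenerate

    def test_constant_nonzero_difference_flagged(self):
        r = ev.paired_t_test([2.0] * 5, [1.0] * 5)
        assert r.degenerate and r.significant and r.p == 0.0

    def test_statistic_matches_hand_formula(self, rng):
        a = rng.normal(0.9, 0.05, 10)
        b = rng.normal(0.85, 0.05, 10)
        r = ev.paired_t_test(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert r.t == pytest.approx(t_hand)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ev.paired_t_test([1.0, 2.0], [1.0])


class TestOverlay:
    def test_perfect_prediction_only_red_on_foreground(self, rng):
        gt = (rng.random((8, 8)) > 0.6).astype(np.uint8)
        out = ev.render_overlay(gt, gt, rng.random((8, 8)))
        red = np.all(out == ev.TP_COLOR, axis=-1)
        assert np.array_equal(red, gt.astype(bool))
        assert not np.all(out == ev.FP_COLOR, axis=-1).any()
        assert not np.all(out == ev.FN_COLOR, axis=-1).any()

    def test_disjoint_masks_blue_and_yellow_only(self):
        pred = np.zeros((4, 4), dtype=np.uint8)
        pred[0] = 1
        gt = np.zeros((4, 4), dtype=np.uint8)
        gt[2] = 1
        out = ev.render_overlay(pred, gt, np.zeros((4, 4)))
        assert np.all(out == ev.FP_COLOR, axis=-1).sum() == 4
        assert np.all(out == ev.FN_COLOR, axis=-1).sum() == 4
        assert np.all(out == ev.TP_COLOR, axis=-1).sum() == 0

    def test_tint_histogram_equals_confusion_counts(self, rng):
        pred = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        gt = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        out = ev.render_overlay(pred, gt, rng.random((16, 16)))
        c = ev.confusion_counts(pred, gt)
        assert np.all(out == ev.TP_COLOR, axis=-1).sum() == c.TP
        assert np.all(out == ev.FP_COLOR, axis=-1).sum() == c.FP
        assert np.all(out == ev.FN_COLOR, axis=-1).sum() == c.FN


def test_evaluate_pairs_aggregates(rng):
    gts = [(rng.random((8, 8)) > 0.5).astype(np.uint8) for _ in range(3)]
    rec = ev.evaluate_pairs(gts, gts)
    assert rec.accuracy == [100.0] * 3
    assert rec.dice == [1.0] * 3
    assert rec.accuracy_stats.std == 0.0
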