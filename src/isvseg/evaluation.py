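"""Pixel-level evaluation: confusion tallies, accuracy and Dice, PR/ROC
curves with trapezoidal AUC, per-image summaries, a paired t-test, and
TP/FP/FN overlay rendering.

Metrics are computed per image and then aggregated (median / mean / sample
standard deviation), never micro-averaged over pooled pixels. Accuracy is
reported on the 0-100 scale, Dice on 0-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "ConfusionCounts",
    "SummaryStats",
    "MetricsRecord",
    "TTestResult",
    "binarize",
    "confusion_counts",
    "pixel_accuracy",
    "dice",
    "pr_curve",
    "roc_curve",
    "auc",
    "summarize",
    "paired_t_test",
    "render_overlay",
    "evaluate_pairs",
    "evaluate_network",
]

# overlay palette (RGB): true/false positives and false negatives
TP_COLOR = (255, 0, 0)      # red
FP_COLOR = (0, 0, 255)      # blue
FN_COLOR = (255, 255, 0)    # yellow


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def binarize(prob_maps: np.ndarray) -> np.ndarray:
    """Two-channel probability maps (..., 2, H, W) -> binary ISV mask.

    A pixel is ISV iff its ISV probability strictly exceeds its non-ISV
    probability; ties go to non-ISV.
    """
    prob_maps = np.asarray(prob_maps)
    axis = prob_maps.ndim - 3
    if prob_maps.shape[axis] != 2:
        raise ValueError("expected two channels (ISV, non-ISV)")
    isv = np.take(prob_maps, 0, axis=axis)
    non = np.take(prob_maps, 1, axis=axis)
    return (isv > non).astype(np.uint8)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return ConfusionCounts(
        TP=int((pred & gt).sum()),
        FP=int((pred & ~gt).sum()),
        TN=int((~pred & ~gt).sum()),
        FN=int((~pred & gt).sum()),
    )


def pixel_accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN), in percent."""
    if c.total == 0:
        raise ValueError("empty region: no pixels to score")
    return 100.0 * (c.TP + c.TN) / c.total


def dice(c: ConfusionCounts) -> float:
    """2 TP / (2 TP + FN + FP); the empty-vs-empty case is defined as 1.0."""
    denom = 2 * c.TP + c.FN + c.FP
    if denom == 0:
        return 1.0
    return 2.0 * c.TP / denom


# ---------------------------------------------------------------------------
# Threshold-sweep curves
# ---------------------------------------------------------------------------

_EXACT_PIXEL_LIMIT = 10_000


def _thresholds(scores: np.ndarray, thresholds) -> np.ndarray:
    if thresholds is not None:
        t = np.asarray(thresholds, dtype=np.float64)
        if (np.diff(t) < 0).any():
            raise ValueError("thresholds must be sorted ascending")
        return t
    grid = np.linspace(0.0, 1.0, 256)
    if scores.size <= _EXACT_PIXEL_LIMIT:
        grid = np.union1d(grid, np.unique(scores))
    return grid


def _sweep(scores: np.ndarray, gt: np.ndarray, thresholds):
    """Vectorized confusion tallies for every threshold (pred = score >= t)."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    gt = np.asarray(gt).astype(bool).ravel()
    if scores.shape != gt.shape:
        raise ValueError("scores and ground truth must be congruent")
    t = _thresholds(scores, thresholds)
    pred = scores[None, :] >= t[:, None]          # (T, P)
    tp = (pred & gt[None, :]).sum(axis=1).astype(float)
    fp = (pred & ~gt[None, :]).sum(axis=1).astype(float)
    pos = float(gt.sum())
    neg = float((~gt).sum())
    return t, tp, fp, pos, neg


def pr_curve(scores: np.ndarray, gt: np.ndarray, thresholds=None
             ) -> tuple[np.ndarray, np.ndarray, int]:
    """Precision/recall over a threshold sweep of the ISV probability map.

    Returns ``(precision, recall, n_dropped)`` where dropped points are
    thresholds with no predicted positives (undefined precision) or a
    positive-free ground truth (undefined recall).
    """
    t, tp, fp, pos, neg = _sweep(scores, gt, thresholds)
    denom = tp + fp
    valid = (denom > 0) & (pos > 0)
    precision = tp[valid] / denom[valid]
    recall = tp[valid] / pos if pos > 0 else np.array([])
    return precision, recall, int((~valid).sum())


def roc_curve(scores: np.ndarray, gt: np.ndarray, thresholds=None
              ) -> tuple[np.ndarray, np.ndarray, int]:
    """ROC (FPR, TPR) over a threshold sweep, anchored at (0,0) and (1,1).

    Points undefined because the ground truth has only one class are dropped
    and counted in the returned flag.
    """
    t, tp, fp, pos, neg = _sweep(scores, gt, thresholds)
    if pos == 0 or neg == 0:
        return np.array([]), np.array([]), len(t)
    fpr = np.concatenate([[0.0], fp / neg, [1.0]])
    tpr = np.concatenate([[0.0], tp / pos, [1.0]])
    order = np.lexsort((tpr, fpr))
    return fpr[order], tpr[order], 0


def auc(x: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal area under a curve, sorted by x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least two curve points")
    order = np.argsort(x, kind="stable")
    return float(np.trapezoid(y[order], x[order]))


# ---------------------------------------------------------------------------
# Aggregation and testing
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    median: float
    mean: float
    std: float   # sample standard deviation (ddof=1); 0 for a single value
    n: int


def summarize(values) -> SummaryStats:
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValueError("nothing to summarize")
    std = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return SummaryStats(median=float(np.median(v)), mean=float(v.mean()),
                        std=std, n=int(v.size))


@dataclass
class MetricsRecord:
    """Per-image accuracy (percent) and Dice with their aggregates."""

    accuracy: list = field(default_factory=list)
    dice: list = field(default_factory=list)
    accuracy_stats: SummaryStats | None = None
    dice_stats: SummaryStats | None = None
    p_value_accuracy: float | None = None
    p_value_dice: float | None = None


@dataclass
class TTestResult:
    t: float
    p: float
    significant: bool      # at the 5% level
    degenerate: bool = False


def paired_t_test(metrics_a, metrics_b, alpha: float = 0.05) -> TTestResult:
    """Two-sided paired t-test on per-image metric differences.

    Zero-variance differences are handled explicitly: all-zero differences
    give p = 1 (no effect), while constant non-zero differences are the
    exact-t limit (p -> 0) and are flagged as degenerate.
    """
    a = np.asarray(list(metrics_a), dtype=np.float64)
    b = np.asarray(list(metrics_b), dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TTestResult(t=0.0, p=1.0, significant=False, degenerate=True)
        return TTestResult(t=np.inf if d.mean() > 0 else -np.inf, p=0.0,
                           significant=True, degenerate=True)
    res = _stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       significant=bool(res.pvalue < alpha))


# ---------------------------------------------------------------------------
# Overlays and end-to-end evaluation
# ---------------------------------------------------------------------------

def render_overlay(pred: np.ndarray, gt: np.ndarray, base: np.ndarray
                   ) -> np.ndarray:
    """Paint TP (red), FP (blue) and FN (yellow) over the grayscale base.

    True negatives keep the (rescaled) base image, so the tint-class counts
    of the rendering equal the confusion counts exactly.
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    base = np.asarray(base, dtype=np.float64)
    if not (pred.shape == gt.shape == base.shape):
        raise ValueError("pred, gt and base must be congruent")
    gray = np.clip(base * 255.0, 0, 254).astype(np.uint8)  # keep 255 for tints
    out = np.stack([gray] * 3, axis=-1)
    out[pred & gt] = TP_COLOR
    out[pred & ~gt] = FP_COLOR
    out[~pred & gt] = FN_COLOR
    return out


def evaluate_pairs(pred_masks, gt_masks) -> MetricsRecord:
    """Per-image accuracy/Dice for paired prediction and ground-truth masks,
    with median/mean/std aggregates."""
    rec = MetricsRecord()
    for p, g in zip(pred_masks, gt_masks):
        c = confusion_counts(p, g)
        rec.accuracy.append(pixel_accuracy(c))
        rec.dice.append(dice(c))
    rec.accuracy_stats = summarize(rec.accuracy)
    rec.dice_stats = summarize(rec.dice)
    return rec


def evaluate_network(network, images: np.ndarray, masks: np.ndarray
                     ) -> tuple[MetricsRecord, np.ndarray]:
    """Run the network (evaluation mode) over patch arrays and score it.

    Returns the metrics record and the stacked ISV probability maps.
    """
    network.eval()
    probs = network(np.asarray(images, dtype=np.float64)).data
    preds = binarize(probs)
    rec = evaluate_pairs(list(preds), list(np.asarray(masks)))
    return rec, probs[:, 0]
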