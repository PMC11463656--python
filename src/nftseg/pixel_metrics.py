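"""Pixel-level evaluation: agreement maps and segmentation scores.

An agreement map classifies every pixel of a predicted mask against the
ground truth as TP / FP / FN / TN; scores derived from the counts are
precision, recall, F1 (= Dice for binary masks), the positive and
negative IOUs and their mean (mIOU), AUROC, and the Tversky index
TP / (TP + alpha*FN + beta*FP), which reduces to F1 at
alpha = beta = 0.5.

A null-model baseline puts F1 into context on heavily imbalanced data:
a random predictor achieves precision equal to the positive-pixel
prevalence, so ``random_baseline_f1(prevalence, recall)`` is the F1 a
prevalence-matched coin flip would earn.

Counts aggregate by summing (micro-averaging) within an ROI; ROI-level
reporting averages scores across ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "AgreementMap",
    "PixelScores",
    "binarize",
    "agreement_map",
    "pixel_scores",
    "tversky_index",
    "auroc",
    "random_baseline_f1",
    "render_agreement_overlay",
    "TP",
    "FP",
    "FN",
    "TN",
]

# categorical codes of the agreement image
TN, TP, FP, FN = 0, 1, 2, 3

#: overlay colors per category (Fig-style palette): TP cyan, FP yellow, FN magenta
OVERLAY_COLORS = {
    TP: (0, 255, 255),
    FP: (255, 255, 0),
    FN: (255, 0, 255),
}


@dataclass
class AgreementMap:
    """Per-pixel TP/FP/FN/TN classification of a prediction vs truth."""

    categories: np.ndarray  # HxW over {TN, TP, FP, FN}
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float = 0.5

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return self.tp, self.fp, self.fn, self.tn


@dataclass
class PixelScores:
    precision: float
    recall: float
    f1: float
    iou_positive: float
    iou_negative: float
    miou: float
    auroc: float | None = None
    tversky: float | None = None
    tversky_alpha: float | None = None
    tversky_beta: float | None = None


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; >= threshold is foreground."""
    prob = np.asarray(prob, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return prob >= threshold


def agreement_map(
    gt: np.ndarray, pred: np.ndarray, threshold: float = 0.5
) -> AgreementMap:
    """Classify each pixel of a binary prediction against ground truth."""
    gt = np.asarray(gt).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    cats = np.full(gt.shape, TN, dtype=np.uint8)
    cats[gt & pred] = TP
    cats[~gt & pred] = FP
    cats[gt & ~pred] = FN
    tp = int((cats == TP).sum())
    fp = int((cats == FP).sum())
    fn = int((cats == FN).sum())
    tn = int((cats == TN).sum())
    return AgreementMap(categories=cats, tp=tp, fp=fp, fn=fn, tn=tn, threshold=threshold)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def tversky_index(
    tp: int, fp: int, fn: int, alpha: float = 0.5, beta: float = 0.5
) -> float:
    """TP / (TP + alpha*FN + beta*FP); Dice/F1 at alpha = beta = 0.5."""
    return _safe_div(tp, tp + alpha * fn + beta * fp, "Tversky index")


def pixel_scores(
    gt_or_counts,
    pred: np.ndarray | None = None,
    scores: np.ndarray | None = None,
    tversky_alpha: float | None = None,
    tversky_beta: float | None = None,
) -> PixelScores:
    """Segmentation scores from (tp, fp, fn, tn) counts or a mask pair.

    Pass either a 4-tuple / :class:`AgreementMap`, or ``(gt, pred)``
    arrays; continuous ``scores`` additionally enable AUROC.  Degenerate
    zero denominators yield 0 with a warning.
    """
    if isinstance(gt_or_counts, AgreementMap):
        tp, fp, fn, tn = gt_or_counts.counts
        gt = None
    elif pred is None:
        tp, fp, fn, tn = (int(v) for v in gt_or_counts)
        if min(tp, fp, fn, tn) < 0:
            raise ValueError("counts must be non-negative")
        gt = None
    else:
        gt = np.asarray(gt_or_counts).astype(bool)
        am = agreement_map(gt, pred)
        tp, fp, fn, tn = am.counts

    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    iou_pos = _safe_div(tp, tp + fp + fn, "positive IOU")
    iou_neg = _safe_div(tn, tn + fp + fn, "negative IOU")

    auc = None
    if scores is not None:
        if gt is None:
            raise ValueError("AUROC needs the ground-truth array, not counts")
        auc = auroc(gt.ravel(), np.asarray(scores, dtype=float).ravel())

    tv = None
    if tversky_alpha is not None or tversky_beta is not None:
        tversky_alpha = 0.5 if tversky_alpha is None else tversky_alpha
        tversky_beta = 0.5 if tversky_beta is None else tversky_beta
        tv = tversky_index(tp, fp, fn, tversky_alpha, tversky_beta)

    return PixelScores(
        precision=precision,
        recall=recall,
        f1=f1,
        iou_positive=iou_pos,
        iou_negative=iou_neg,
        miou=(iou_pos + iou_neg) / 2.0,
        auroc=auc,
        tversky=tv,
        tversky_alpha=tversky_alpha,
        tversky_beta=tversky_beta,
    )


def auroc(gt: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve with midrank tie handling.

    Equals the normalized Mann-Whitney U statistic.  Requires both
    classes present in the ground truth.
    """
    gt = np.asarray(gt).astype(bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if gt.all() or not gt.any():
        raise ValueError("AUROC undefined: ground truth contains a single class")
    return float(roc_auc_score(gt, scores))


def random_baseline_f1(prevalence: float, recall: float = 0.5) -> float:
    """F1 of a prevalence-matched null model.

    A random predictor's precision equals the positive-class prevalence;
    with the stated recall its F1 is 2PR/(P+R).  This is the floor any
    useful segmenter must clear on imbalanced data.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    if not 0 < recall <= 1:
        raise ValueError("recall must lie in (0, 1]")
    p = prevalence
    return 2.0 * p * recall / (p + recall)


def render_agreement_overlay(
    rgb: np.ndarray, amap: AgreementMap, alpha: float = 0.5
) -> np.ndarray:
    """Blend TP (cyan), FP (yellow) and FN (magenta) over the source image.

    TN pixels are untouched.  Blend is (1-alpha)*src + alpha*color.
    """
    rgb = np.asarray(rgb)
    if rgb.shape[:2] != amap.categories.shape:
        raise ValueError("image and agreement map dims must match")
    out = rgb.astype(float).copy()
    for cat, color in OVERLAY_COLORS.items():
        sel = amap.categories == cat
        out[sel] = (1 - alpha) * out[sel] + alpha * np.array(color, dtype=float)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
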