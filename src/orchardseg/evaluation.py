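"""Segmentation quality metrics: pixel overlap, tree counting, ROC/AUC.

Pixel metrics (IoU, P_I, R_I, F1_I) score the foreground mask against a
ground-truth mask.  Tree-count metrics (CTR, P_C, R_C, F1_C) score how
many individual crowns were recovered: predicted and true regions are
matched one-to-one greedily by descending IoU, a pair with IoU at or
above the matching threshold counts as a true positive.  All metrics are
reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .imaging import RegionSet

__all__ = [
    "PixelMetrics",
    "CountMetrics",
    "pixel_metrics",
    "match_regions",
    "tree_count_metrics",
    "roc_auc",
]

MATCH_IOU: float = 0.5


@dataclass(frozen=True)
class PixelMetrics:
    iou: float
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class CountMetrics:
    ctr: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


def _f1(p: float, r: float) -> float:
    return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


def pixel_metrics(pred: np.ndarray, truth: np.ndarray) -> PixelMetrics:
    """Pixel-level IoU, precision, recall and F1 in percent.

    Two empty masks agree perfectly (all metrics 100 by convention).
    """
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    union = tp + fp + fn
    if union == 0:
        return PixelMetrics(100.0, 100.0, 100.0, 100.0)
    iou = 100.0 * tp / union
    prec = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else 0.0
    rec = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return PixelMetrics(iou, prec, rec, _f1(prec, rec))


def _region_masks(rs: RegionSet | list[np.ndarray]) -> list[np.ndarray]:
    if isinstance(rs, RegionSet):
        return [rs.region_mask(r.label) for r in rs.regions]
    return [np.asarray(m, dtype=bool) for m in rs]


def match_regions(
    pred: RegionSet | list[np.ndarray],
    truth: RegionSet | list[np.ndarray],
    iou_threshold: float = MATCH_IOU,
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of predicted to true regions.

    Candidate pairs are sorted by descending IoU; each region can be used
    at most once; pairs below *iou_threshold* are discarded.  Returns
    ``(pred_index, truth_index, iou)`` triples.
    """
    pm = _region_masks(pred)
    tm = _region_masks(truth)
    pairs = []
    for i, p in enumerate(pm):
        for j, t in enumerate(tm):
            inter = int(np.count_nonzero(p & t))
            if inter == 0:
                continue
            union = int(np.count_nonzero(p | t))
            iou = inter / union
            if iou >= iou_threshold:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for iou, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches.append((i, j, iou))
    return matches


def tree_count_metrics(
    pred: RegionSet | list[np.ndarray],
    truth: RegionSet | list[np.ndarray],
    iou_threshold: float = MATCH_IOU,
) -> CountMetrics:
    """Tree-count CTR, precision, recall and F1 in percent.

    CTR = matched true trees / total true trees; unmatched predictions
    are false positives, unmatched true trees false negatives.
    """
    pm = _region_masks(pred)
    tm = _region_masks(truth)
    matches = match_regions(pm, tm, iou_threshold)
    tp = len(matches)
    fp = len(pm) - tp
    fn = len(tm) - tp
    prec = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else 0.0
    rec = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else 0.0
    ctr = 100.0 * tp / len(tm) if tm else 0.0
    return CountMetrics(ctr, prec, rec, _f1(prec, rec), tp, fp, fn)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC curve and AUC (percent) for region decision scores.

    Sweeps every score threshold; AUC by the trapezoid rule with tied
    scores averaged (equivalently the Mann–Whitney U statistic over
    positive/negative score pairs).  Requires both classes present.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y.astype(int), s)
    auc = 100.0 * float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr
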