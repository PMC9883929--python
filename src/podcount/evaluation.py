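"""Detection and counting metrics.

Detections are matched to ground truth greedily in descending score order
at IoU >= 0.5, one-to-one. AP50 is reported in two dialects: the COCO
101-point interpolation and the VOC 11-point interpolation (a continuous
area-under-envelope variant is also available). Counting quality uses
R-squared (squared Pearson correlation of predicted vs. true counts),
MAE, MAPE (in percent, excluding zero-count images), and RMSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .annotations_io import ImageAnnotation
from .boxes import Box, box_iou

__all__ = [
    "MatchResult",
    "MetricsReport",
    "match_detections",
    "average_precision_50",
    "count_from_detections",
    "counting_metrics",
    "evaluate_detections",
]

IOU_THRESHOLD = 0.5


@dataclass
class MatchResult:
    """Per-image true/false positives and missed ground truths at IoU 0.5."""

    true_positives: list[Box] = field(default_factory=list)
    false_positives: list[Box] = field(default_factory=list)
    false_negatives: list[Box] = field(default_factory=list)
    # (score, is_tp) pairs for every detection, for PR-curve construction
    scored_flags: list[tuple[float, bool]] = field(default_factory=list)
    n_gt: int = 0

    @property
    def precision(self) -> float:
        tp, fp = len(self.true_positives), len(self.false_positives)
        return tp / (tp + fp) if tp + fp else 0.0

    @property
    def recall(self) -> float:
        return len(self.true_positives) / self.n_gt if self.n_gt else 0.0


@dataclass
class MetricsReport:
    ap50_coco: float
    ap50_voc: float
    precision: float
    recall: float
    r_squared: Optional[float] = None
    mae: Optional[float] = None
    mape_percent: Optional[float] = None
    rmse: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def table(self) -> str:
        rows = [(k, v) for k, v in asdict(self).items() if v is not None]
        w = max(len(k) for k, _ in rows)
        return "\n".join(f"{k.ljust(w)}  {v:.4f}" for k, v in rows)


def match_detections(
    dets: Sequence[Box],
    gts: Sequence[Box],
    iou_threshold: float = IOU_THRESHOLD,
) -> MatchResult:
    """Greedy one-to-one matching in descending score order.

    Each detection claims the unmatched ground-truth box of highest IoU,
    provided that IoU reaches the threshold; otherwise it is a false
    positive. Unclaimed ground truths are false negatives.
    """
    if any(d.score is None for d in dets):
        raise ValueError("detections must carry scores")
    result = MatchResult(n_gt=len(gts))
    taken = [False] * len(gts)
    for det in sorted(dets, key=lambda d: -d.score):
        best, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if taken[j]:
                continue
            v = box_iou(det, gt)
            if v > best_iou:
                best, best_iou = j, v
        if best >= 0 and best_iou >= iou_threshold:
            taken[best] = True
            result.true_positives.append(det)
            result.scored_flags.append((det.score, True))
        else:
            result.false_positives.append(det)
            result.scored_flags.append((det.score, False))
    result.false_negatives = [gt for j, gt in enumerate(gts) if not taken[j]]
    return result


def _pr_curve(matches: Sequence[MatchResult]):
    """Global score-ranked precision/recall arrays over a dataset."""
    n_gt = sum(m.n_gt for m in matches)
    if n_gt == 0:
        raise ValueError("AP undefined: no ground-truth boxes")
    flags = sorted(
        (pair for m in matches for pair in m.scored_flags), key=lambda p: -p[0]
    )
    tp = np.cumsum([f for _, f in flags]) if flags else np.array([])
    fp = np.cumsum([not f for _, f in flags]) if flags else np.array([])
    if len(flags) == 0:
        return np.array([0.0]), np.array([0.0])
    recall = tp / n_gt
    precision = tp / (tp + fp)
    return recall, precision


def average_precision_50(
    matches: Sequence[MatchResult], dialect: str = "coco"
) -> float:
    """AP at IoU 0.5 from the global PR curve.

    ``coco``: 101-point interpolation (mean of the precision envelope at
    recalls 0.00, 0.01, ..., 1.00). ``voc``: classic 11-point interpolation
    at recalls 0.0, 0.1, ..., 1.0. ``voc_continuous``: area under the
    monotone precision envelope.
    """
    recall, precision = _pr_curve(matches)
    # monotone non-increasing precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if dialect == "coco":
        grid = np.linspace(0.0, 1.0, 101)
    elif dialect == "voc":
        grid = np.linspace(0.0, 1.0, 11)
    elif dialect == "voc_continuous":
        r = np.concatenate([[0.0], recall, [1.0]])
        p = np.concatenate([[env[0] if env.size else 0.0], env, [0.0]])
        penv = np.maximum.accumulate(p[::-1])[::-1]
        return float(np.sum((r[1:] - r[:-1]) * penv[1:]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    interp = np.zeros_like(grid)
    for i, r in enumerate(grid):
        # tolerance guards against grid values like 0.6000000000000001
        mask = recall >= r - 1e-12
        interp[i] = env[mask].max() if mask.any() else 0.0
    return float(interp.mean())


def count_from_detections(dets: Sequence[Box], conf_threshold: float) -> int:
    """Per-image count: detections at or above the confidence threshold."""
    return sum(1 for d in dets if (d.score or 0.0) >= conf_threshold)


def counting_metrics(
    predicted: Sequence[float], actual: Sequence[float]
) -> tuple[float, float, float, float]:
    """(r_squared, mae, mape_percent, rmse) between count series.

    R-squared is the squared Pearson correlation of the two series. MAPE is
    in percent and averages only over images with a nonzero true count.
    """
    p = np.asarray(predicted, dtype=np.float64)
    a = np.asarray(actual, dtype=np.float64)
    if p.shape != a.shape:
        raise ValueError("predicted and actual must have equal length")
    if p.size < 2:
        raise ValueError("need at least 2 images for counting metrics")
    err = p - a
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    nz = a > 0
    if not nz.any():
        raise ValueError("MAPE undefined: all true counts are zero")
    mape = float(100.0 * (np.abs(err[nz]) / a[nz]).mean())
    if np.std(p) == 0 or np.std(a) == 0:
        raise ValueError("R-squared undefined: zero variance in counts")
    r = float(np.corrcoef(p, a)[0, 1])
    return r * r, mae, mape, rmse


def evaluate_detections(
    detections: Sequence[Sequence[Box]],
    annotations: Sequence[ImageAnnotation],
    conf_threshold: float = 0.25,
    iou_threshold: float = IOU_THRESHOLD,
    voc_dialect: str = "voc",
) -> MetricsReport:
    """Full metric report for per-image detection lists vs. ground truth."""
    if len(detections) != len(annotations):
        raise ValueError("detections and annotations must align per image")
    matches = [
        match_detections(dets, ann.boxes, iou_threshold)
        for dets, ann in zip(detections, annotations)
    ]
    tp = sum(len(m.true_positives) for m in matches)
    fp = sum(len(m.false_positives) for m in matches)
    fn = sum(len(m.false_negatives) for m in matches)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    report = MetricsReport(
        ap50_coco=average_precision_50(matches, "coco"),
        ap50_voc=average_precision_50(matches, voc_dialect),
        precision=precision,
        recall=recall,
    )
    if len(annotations) >= 2:
        counts_pred = [count_from_detections(d, conf_threshold) for d in detections]
        counts_true = [a.count() for a in annotations]
        try:
            r2, mae, mape, rmse = counting_metrics(counts_pred, counts_true)
            report.r_squared, report.mae = r2, mae
            report.mape_percent, report.rmse = mape, rmse
        except ValueError:
            pass  # degenerate count series; detection metrics still stand
    return report
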