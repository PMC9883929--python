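"""Loss functions: the count (number) loss, the detection loss, and their
weighted combination.

The count head emits 300 unnormalized logits over possible per-image counts
0..299. The logits are log-softmax normalized and scored by negative
log-likelihood at the true count (the number of ground-truth boxes), i.e.
standard cross-entropy over count classes; with unit class weights this is
the batch-mean negative log-probability. The total training loss is

    L_total = lambda_num * L_num + lambda_yolo * L_yolo

with lambda_num = 0.3 and lambda_yolo = 1.0.

The detection loss follows the anchor-free baseline: positives are chosen
by dynamic-k (SimOTA-style) assignment over a centre-prior candidate
region, scored with (1 - IoU) box regression, binary cross-entropy
objectness over all locations, and binary cross-entropy classification at
positives, all normalized by the number of positives. A simplified
fixed-radius centre assignment is available as a test mode so tiny
instances can be checked against a brute-force oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .annotations_io import ImageAnnotation
from .autograd import Tensor, _stable_sigmoid, concat
from .boxes import Box, box_iou, pairwise_iou

__all__ = [
    "LAMBDA_NUM",
    "LAMBDA_YOLO",
    "NumberLossInputs",
    "LossBreakdown",
    "log_softmax_300",
    "number_loss",
    "total_loss",
    "detection_loss",
    "iou",
]

LAMBDA_NUM = 0.3
LAMBDA_YOLO = 1.0
N_COUNT = 300
REG_WEIGHT = 5.0
CENTER_RADIUS = 2.5  # stride units, centre-prior candidate region
EPS = 1e-8


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes (0 when disjoint)."""
    return box_iou(a, b)


@dataclass
class NumberLossInputs:
    logits: Union[Tensor, np.ndarray]  # (B, 300)
    targets: np.ndarray  # (B,) integer counts in [0, 299]
    weights: Optional[np.ndarray] = None  # per-class weights, default all 1

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.int64)
        if self.targets.ndim != 1 or self.targets.size < 1:
            raise ValueError("targets must be a non-empty 1-D integer array")
        if self.targets.min() < 0 or self.targets.max() >= N_COUNT:
            raise ValueError(f"targets must lie in [0, {N_COUNT - 1}]")
        if self.weights is None:
            self.weights = np.ones(N_COUNT, dtype=np.float32)


@dataclass
class LossBreakdown:
    l_num: float
    l_yolo: float
    lambda_num: float = LAMBDA_NUM
    lambda_yolo: float = LAMBDA_YOLO
    components: dict = field(default_factory=dict)

    @property
    def l_total(self) -> float:
        return self.lambda_num * self.l_num + self.lambda_yolo * self.l_yolo


def log_softmax_300(logits: Union[Tensor, np.ndarray]) -> Union[Tensor, np.ndarray]:
    """Stable log-softmax over the 300 count classes (last axis)."""
    if isinstance(logits, Tensor):
        if logits.shape[-1] != N_COUNT:
            raise ValueError(f"expected last axis {N_COUNT}, got {logits.shape[-1]}")
        return logits.log_softmax(axis=-1)
    x = np.asarray(logits, dtype=np.float64)
    if x.shape[-1] != N_COUNT:
        raise ValueError(f"expected last axis {N_COUNT}, got {x.shape[-1]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite logits")
    shifted = x - x.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


def clip_counts(counts: np.ndarray) -> np.ndarray:
    """Clip counts above 299 into the model's count-class range, warning."""
    counts = np.asarray(counts, dtype=np.int64)
    if (counts >= N_COUNT).any():
        warnings.warn(
            f"{int((counts >= N_COUNT).sum())} ground-truth counts exceed "
            f"{N_COUNT - 1}; clipping",
            stacklevel=2,
        )
        counts = np.minimum(counts, N_COUNT - 1)
    return counts


def number_loss(inputs: NumberLossInputs) -> Union[Tensor, float]:
    """Weighted negative log-likelihood at the true counts.

    L = sum_b(-w[y_b] * logp[b, y_b]) / sum_b w[y_b]; with unit weights this
    is the batch-mean cross-entropy over 300 count classes.
    """
    logp = log_softmax_300(inputs.logits)
    b_idx = np.arange(inputs.targets.size)
    w = inputs.weights[inputs.targets].astype(np.float32)
    wsum = float(w.sum())
    if isinstance(logp, Tensor):
        picked = logp[(b_idx, inputs.targets)]
        return (picked * (-w)).sum() * (1.0 / wsum)
    return float(-(w * logp[b_idx, inputs.targets]).sum() / wsum)


def total_loss(l_num, l_yolo, lambda_num: float = LAMBDA_NUM, lambda_yolo: float = LAMBDA_YOLO):
    """Combined multi-task loss; works on floats or autograd tensors."""
    return lambda_num * l_num + lambda_yolo * l_yolo


# -- detection loss --------------------------------------------------------


def _flatten_raw(scales: Sequence[dict], strides: Sequence[int]):
    """Flatten per-scale maps into per-anchor tensors plus grid metadata."""
    regs, objs, clss = [], [], []
    centers, stride_arr = [], []
    for maps, s in zip(scales, strides):
        reg, obj, cls = maps["reg"], maps["obj"], maps["cls"]
        n, _, h, w = reg.shape
        regs.append(reg.transpose(0, 2, 3, 1).reshape(n, h * w, 4))
        objs.append(obj.transpose(0, 2, 3, 1).reshape(n, h * w, 1))
        clss.append(cls.transpose(0, 2, 3, 1).reshape(n, h * w, cls.shape[1]))
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        centers.append(np.stack([gx.ravel(), gy.ravel()], axis=-1).astype(np.float64))
        stride_arr.append(np.full(h * w, s, dtype=np.float64))
    return (
        concat(regs, axis=1),
        concat(objs, axis=1),
        concat(clss, axis=1),
        np.concatenate(centers, axis=0),
        np.concatenate(stride_arr, axis=0),
    )


def _decode_np(reg: np.ndarray, grid: np.ndarray, stride: np.ndarray) -> np.ndarray:
    """(A,4) raw regression -> (A,4) xyxy boxes, numpy (no grad)."""
    cx = (reg[:, 0] + grid[:, 0]) * stride
    cy = (reg[:, 1] + grid[:, 1]) * stride
    bw = np.exp(np.clip(reg[:, 2], -20, 10)) * stride
    bh = np.exp(np.clip(reg[:, 3], -20, 10)) * stride
    return np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=-1)


def _sigmoid_np(x):
    return _stable_sigmoid(x)


def _assign_simota(
    gt: np.ndarray, pred_boxes: np.ndarray, obj: np.ndarray, cls: np.ndarray,
    grid: np.ndarray, stride: np.ndarray,
) -> np.ndarray:
    """Dynamic-k assignment. Returns (A,) int array of gt index or -1."""
    A = grid.shape[0]
    assign = np.full(A, -1, dtype=np.int64)
    G = gt.shape[0]
    if G == 0:
        return assign
    cxa = (grid[:, 0] + 0.5) * stride
    cya = (grid[:, 1] + 0.5) * stride
    in_box = (
        (cxa[None] >= gt[:, None, 0]) & (cxa[None] < gt[:, None, 2])
        & (cya[None] >= gt[:, None, 1]) & (cya[None] < gt[:, None, 3])
    )  # (G, A)
    gcx = (gt[:, 0] + gt[:, 2]) / 2
    gcy = (gt[:, 1] + gt[:, 3]) / 2
    r = CENTER_RADIUS * stride
    in_center = (
        (np.abs(cxa[None] - gcx[:, None]) < r[None])
        & (np.abs(cya[None] - gcy[:, None]) < r[None])
    )
    cand = (in_box | in_center).any(axis=0)
    if not cand.any():
        # degenerate (sub-cell gt far off grid): fall back to nearest anchors
        cand = np.zeros(A, dtype=bool)
        cand[np.argmin((cxa[None] - gcx[:, None]) ** 2 + (cya[None] - gcy[:, None]) ** 2, axis=1)] = True
    cidx = np.where(cand)[0]
    ious = pairwise_iou(gt, pred_boxes[cidx])  # (G, C)
    p = np.sqrt(
        _sigmoid_np(cls[cidx, 0]) * _sigmoid_np(obj[cidx, 0])
    )  # single-class joint prob
    cls_cost = -np.log(p + EPS)[None, :].repeat(G, axis=0)
    iou_cost = -np.log(ious + EPS)
    both = in_box[:, cidx] & in_center[:, cidx]
    cost = cls_cost + 3.0 * iou_cost + 1e5 * (~both)
    # dynamic k per gt from the total overlap mass
    topk = min(10, cidx.size)
    ks = np.maximum(np.sort(ious, axis=1)[:, -topk:].sum(axis=1).astype(np.int64), 1)
    match = np.zeros_like(cost, dtype=bool)
    for g in range(G):
        k = min(int(ks[g]), cidx.size)
        match[g, np.argpartition(cost[g], k - 1)[:k]] = True
    # an anchor claimed by several gts goes to its cheapest
    multi = match.sum(axis=0) > 1
    if multi.any():
        best = np.argmin(cost[:, multi], axis=0)
        match[:, multi] = False
        match[best, np.where(multi)[0]] = True
    g_idx, c_idx = np.where(match)
    assign[cidx[c_idx]] = g_idx
    return assign


def _assign_center(
    gt: np.ndarray, grid: np.ndarray, stride: np.ndarray, radius: float = 1.5
) -> np.ndarray:
    """Test-mode assignment: anchors within ``radius`` stride units of a gt
    centre are positive for the nearest gt. Deliberately simple so a
    brute-force oracle can reproduce it."""
    A = grid.shape[0]
    assign = np.full(A, -1, dtype=np.int64)
    if gt.shape[0] == 0:
        return assign
    cxa = (grid[:, 0] + 0.5) * stride
    cya = (grid[:, 1] + 0.5) * stride
    gcx = (gt[:, 0] + gt[:, 2]) / 2
    gcy = (gt[:, 1] + gt[:, 3]) / 2
    dx = np.abs(cxa[None] - gcx[:, None])
    dy = np.abs(cya[None] - gcy[:, None])
    near = (dx < radius * stride[None]) & (dy < radius * stride[None])
    dist = dx**2 + dy**2
    dist[~near] = np.inf
    best = dist.argmin(axis=0)
    assign[np.isfinite(dist.min(axis=0))] = best[np.isfinite(dist.min(axis=0))]
    return assign


def detection_loss(
    raw: dict,
    targets: Sequence[ImageAnnotation],
    strides: Sequence[int] = (8, 16, 32),
    assigner: str = "simota",
) -> dict:
    """Anchor-free detection loss over a batch.

    Returns a dict with autograd scalars: ``iou``, ``obj``, ``cls``,
    ``l_yolo`` and the positive count ``num_fg``.
    """
    scales = raw["scales"]
    reg_t, obj_t, cls_t, grid, stride = _flatten_raw(scales, strides)
    n = reg_t.shape[0]
    if len(targets) != n:
        raise ValueError(f"batch mismatch: {n} predictions vs {len(targets)} targets")
    A = reg_t.shape[1]

    obj_target = np.zeros((n, A, 1), dtype=np.float32)
    pos_img, pos_anchor, pos_gt = [], [], []
    for i, ann in enumerate(targets):
        gt = np.array([b.as_array() for b in ann.boxes], dtype=np.float64).reshape(-1, 4)
        if assigner == "simota":
            pred_np = _decode_np(reg_t.data[i], grid, stride)
            assign = _assign_simota(
                gt, pred_np, obj_t.data[i], cls_t.data[i], grid, stride
            )
        elif assigner == "center":
            assign = _assign_center(gt, grid, stride)
        else:
            raise ValueError(f"unknown assigner {assigner!r}")
        pos = np.where(assign >= 0)[0]
        obj_target[i, pos, 0] = 1.0
        if pos.size:
            pos_img.append(np.full(pos.size, i))
            pos_anchor.append(pos)
            pos_gt.append(gt[assign[pos]])

    num_fg = int(sum(p.size for p in pos_anchor))
    norm = 1.0 / max(num_fg, 1)
    obj_loss = obj_t.bce_with_logits(obj_target).sum() * norm

    if num_fg == 0:
        zero = obj_loss * 0.0
        l_yolo = obj_loss
        return {
            "iou": zero, "obj": obj_loss, "cls": zero, "l_yolo": l_yolo,
            "num_fg": 0,
        }

    ii = np.concatenate(pos_img)
    aa = np.concatenate(pos_anchor)
    gt_boxes = np.concatenate(pos_gt, axis=0)

    reg_pos = reg_t[(ii, aa)]  # (P, 4)
    gx, gy = grid[aa, 0], grid[aa, 1]
    ss = stride[aa]
    cx = (reg_pos[:, 0] + gx) * ss
    cy = (reg_pos[:, 1] + gy) * ss
    bw = reg_pos[:, 2].clip(-20.0, 10.0).exp() * ss
    bh = reg_pos[:, 3].clip(-20.0, 10.0).exp() * ss
    x0, x1 = cx - bw * 0.5, cx + bw * 0.5
    y0, y1 = cy - bh * 0.5, cy + bh * 0.5
    ix = x1.minimum(gt_boxes[:, 2]) - x0.maximum(gt_boxes[:, 0])
    iy = y1.minimum(gt_boxes[:, 3]) - y0.maximum(gt_boxes[:, 1])
    inter = ix.relu() * iy.relu()
    area_p = bw * bh
    area_g = (gt_boxes[:, 2] - gt_boxes[:, 0]) * (gt_boxes[:, 3] - gt_boxes[:, 1])
    union = area_p + area_g - inter + EPS
    iou_vals = inter / union
    iou_loss = (1.0 - iou_vals).sum() * norm

    cls_pos = cls_t[(ii, aa)]  # (P, ncls); single class -> target 1
    cls_target = np.ones(cls_pos.shape, dtype=np.float32)
    cls_loss = cls_pos.bce_with_logits(cls_target).sum() * norm

    l_yolo = REG_WEIGHT * iou_loss + obj_loss + cls_loss
    return {
        "iou": iou_loss,
        "obj": obj_loss,
        "cls": cls_loss,
        "l_yolo": l_yolo,
        "num_fg": num_fg,
    }
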