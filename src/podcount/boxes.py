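"""Axis-aligned box geometry.

Internal convention everywhere in this package: 0-based, half-open,
continuous pixel coordinates — a box covers [x_min, x_max) x [y_min, y_max),
so its area is (x_max - x_min) * (y_max - y_min) with no +1 terms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["Box", "box_iou", "pairwise_iou", "greedy_nms"]


@dataclass(frozen=True)
class Box:
    """One annotated or detected rectangle, in pixel coordinates.

    ``score`` is the detection confidence in [0, 1]; ground-truth boxes
    leave it as ``None``.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: Optional[float] = None
    label: str = "pod"

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def shifted(self, dx: float, dy: float) -> "Box":
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )

    def scaled(self, sx: float, sy: float) -> "Box":
        return replace(
            self,
            x_min=self.x_min * sx,
            y_min=self.y_min * sy,
            x_max=self.x_max * sx,
            y_max=self.y_max * sy,
        )

    def clipped(self, width: float, height: float) -> Optional["Box"]:
        """Clip to [0, width) x [0, height); None if nothing remains."""
        x0, y0 = max(self.x_min, 0.0), max(self.y_min, 0.0)
        x1, y1 = min(self.x_max, float(width)), min(self.y_max, float(height))
        if x0 >= x1 or y0 >= y1:
            return None
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x_min, self.y_min, self.x_max, self.y_max], dtype=np.float64
        )


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (N,4) and (M,4) arrays of [x0,y0,x1,y1] boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(
        a[:, None, 0], b[None, :, 0]
    )
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(
        a[:, None, 1], b[None, :, 1]
    )
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def greedy_nms(boxes: list[Box], iou_threshold: float) -> list[Box]:
    """Class-agnostic greedy non-maximum suppression on scored boxes."""
    order = sorted(boxes, key=lambda b: -(b.score or 0.0))
    kept: list[Box] = []
    for cand in order:
        if all(box_iou(cand, k) <= iou_threshold for k in kept):
            kept.append(cand)
    return kept
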