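"""Bounding-box geometry, IoU-family losses, and bipartite set matching.

Boxes are normalized center format ``(cx, cy, w, h)`` with ``cx, cy ∈ [0, 1]``
and ``w, h > 0``.  All scalar operations are thin wrappers over vectorized
array kernels so the same code path serves both the pure-function API and the
detector's batched loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "BBox",
    "LossWeights",
    "MatchResult",
    "iou",
    "giou",
    "ciou_aspect_term",
    "ciou_loss",
    "box_loss",
    "hungarian_match",
    "cxcywh_to_xyxy",
    "xyxy_to_cxcywh",
    "cxcywh_norm_to_coco",
    "coco_to_cxcywh_norm",
]


@dataclass(frozen=True)
class BBox:
    """Normalized center-format box."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"degenerate box: w={self.w}, h={self.h}")

    def as_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.w, self.h], dtype=float)

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) corner form."""
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )


@dataclass(frozen=True)
class LossWeights:
    lambda_ciou: float = 2.0
    lambda_l1: float = 5.0

    def __post_init__(self) -> None:
        if self.lambda_ciou < 0 or self.lambda_l1 < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_ciou == 0 and self.lambda_l1 == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class MatchResult:
    """Injective assignment target index -> prediction index."""

    assignment: Dict[int, int]
    total_cost: float


def _as_batch(b) -> np.ndarray:
    if isinstance(b, BBox):
        return b.as_array()[None, :]
    arr = np.asarray(b, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[-1] != 4:
        raise ValueError("boxes must have 4 components (cx, cy, w, h)")
    if np.any(arr[..., 2:] <= 0):
        raise ValueError("degenerate box: nonpositive width or height")
    return arr


def _maybe_scalar(x: np.ndarray, a, b) -> float | np.ndarray:
    if isinstance(a, BBox) and isinstance(b, BBox):
        return float(x[0])
    return x


def cxcywh_to_xyxy(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    half = boxes[..., 2:] / 2
    return np.concatenate([boxes[..., :2] - half, boxes[..., :2] + half], axis=-1)


def xyxy_to_cxcywh(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    wh = boxes[..., 2:] - boxes[..., :2]
    return np.concatenate([(boxes[..., :2] + boxes[..., 2:]) / 2, wh], axis=-1)


def cxcywh_norm_to_coco(boxes: np.ndarray, image_side: int) -> np.ndarray:
    """Normalized center boxes -> COCO ``[x, y, w, h]`` pixels, top-left origin."""
    xyxy = cxcywh_to_xyxy(np.asarray(boxes, dtype=float)) * image_side
    out = xyxy.copy()
    out[..., 2:] = xyxy[..., 2:] - xyxy[..., :2]
    return out


def coco_to_cxcywh_norm(boxes: np.ndarray, image_side: int) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    cx = (boxes[..., 0] + boxes[..., 2] / 2) / image_side
    cy = (boxes[..., 1] + boxes[..., 3] / 2) / image_side
    return np.stack([cx, cy, boxes[..., 2] / image_side, boxes[..., 3] / image_side], axis=-1)


def _iou_parts(a: np.ndarray, b: np.ndarray):
    ax = cxcywh_to_xyxy(a)
    bx = cxcywh_to_xyxy(b)
    lt = np.maximum(ax[..., :2], bx[..., :2])
    rb = np.minimum(ax[..., 2:], bx[..., 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = a[..., 2] * a[..., 3]
    area_b = b[..., 2] * b[..., 3]
    union = area_a + area_b - inter
    hull_lt = np.minimum(ax[..., :2], bx[..., :2])
    hull_rb = np.maximum(ax[..., 2:], bx[..., 2:])
    return inter / union, union, hull_lt, hull_rb


def iou(a, b):
    """Intersection over union; symmetric, in [0, 1]."""
    aa, bb = _as_batch(a), _as_batch(b)
    val, _, _, _ = _iou_parts(aa, bb)
    return _maybe_scalar(val, a, b)


def giou(a, b):
    """Generalized IoU: IoU minus hull-slack penalty; in (−1, 1]."""
    aa, bb = _as_batch(a), _as_batch(b)
    i, union, hull_lt, hull_rb = _iou_parts(aa, bb)
    hull_wh = hull_rb - hull_lt
    hull_area = hull_wh[..., 0] * hull_wh[..., 1]
    val = i - (hull_area - union) / hull_area
    return _maybe_scalar(val, a, b)


def ciou_aspect_term(target, pred):
    """Aspect-ratio mismatch term v = (4/π²)(arctan(w1/h1) − arctan(w/h))²."""
    t, p = _as_batch(target), _as_batch(pred)
    d = np.arctan2(t[..., 2], t[..., 3]) - np.arctan2(p[..., 2], p[..., 3])
    val = (4.0 / np.pi**2) * d**2
    return _maybe_scalar(val, target, pred)


def ciou_loss(target, pred):
    """Complete-IoU loss: 1 − IoU + D²/C² + a·v.

    D is the Euclidean distance between box centers, C the diagonal of the
    smallest enclosing box, v the aspect term, and a = v / ((1 − IoU) + v) the
    trade-off coefficient (a·v defined as 0 when IoU = 1 and v = 0).
    """
    t, p = _as_batch(target), _as_batch(pred)
    i, _, hull_lt, hull_rb = _iou_parts(t, p)
    d2 = np.sum((t[..., :2] - p[..., :2]) ** 2, axis=-1)
    hull_wh = hull_rb - hull_lt
    c2 = hull_wh[..., 0] ** 2 + hull_wh[..., 1] ** 2
    v = (4.0 / np.pi**2) * (
        np.arctan2(t[..., 2], t[..., 3]) - np.arctan2(p[..., 2], p[..., 3])
    ) ** 2
    denom = (1.0 - i) + v
    alpha = np.where(denom > 0, v / np.where(denom > 0, denom, 1.0), 0.0)
    val = 1.0 - i + d2 / c2 + alpha * v
    return _maybe_scalar(val, target, pred)


def box_loss(target, pred, weights: LossWeights = LossWeights()):
    """Combined border loss λ_CIOU·L_CIOU + λ_l1·‖Δ(cx,cy,w,h)‖₁."""
    t, p = _as_batch(target), _as_batch(pred)
    l1 = np.sum(np.abs(t - p), axis=-1)
    val = weights.lambda_ciou * ciou_loss(t, p) + weights.lambda_l1 * l1
    return _maybe_scalar(val, target, pred)


def hungarian_match(cost: np.ndarray) -> MatchResult:
    """Optimal injective assignment of targets (rows) to predictions (cols).

    Minimizes the summed cost; covers every target when there are at least as
    many predictions as targets.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return MatchResult(assignment={}, total_cost=0.0)
    if cost.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(cost)
    return MatchResult(
        assignment={int(r): int(c) for r, c in zip(rows, cols)},
        total_cost=float(cost[rows, cols].sum()),
    )
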