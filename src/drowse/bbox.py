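"""Axis-aligned bounding-box geometry: IoU, an improved regression loss, NMS.

The loss augments 1 - IoU with a normalised centre-distance penalty and two
arctan aspect-ratio penalties (one quartic and damped by 1 - IoU, one
quadratic).  It is implemented verbatim in that form; a standard CIoU
variant is available behind the ``variant`` flag for comparison.

Boxes use the corner convention ``(x1, y1, x2, y2)`` with ``x2 > x1`` and
``y2 > y1``; coordinates are continuous pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateGeometryError

__all__ = ["BBox", "iou", "libox", "nms"]


@dataclass(frozen=True)
class BBox:
    x1: float
    y1: float
    x2: float
    y2: float
    score: float | None = None

    def __post_init__(self) -> None:
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise DegenerateGeometryError(
                f"box must have positive extent, got {(self.x1, self.y1, self.x2, self.y2)}"
            )
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def translate(self, dx: float, dy: float) -> "BBox":
        return BBox(self.x1 + dx, self.y1 + dy, self.x2 + dx, self.y2 + dy, self.score)


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when equal."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def libox(pred: BBox, gt: BBox, *, variant: str = "improved") -> float:
    """Bounding-box regression loss between a predicted and a reference box.

    ``variant="improved"`` (default) evaluates, with
    d = arctan(w_gt / h_gt) - arctan(w_pred / h_pred)::

        1 - IoU + rho^2 / c^2 + (4 / pi^2) d^4 (1 - IoU) + (4 / pi^2) d^2

    where rho is the distance between box centres and c the diagonal of the
    smallest box enclosing both.  ``variant="ciou"`` gives the standard
    complete-IoU loss with the trade-off weight alpha = v / ((1 - IoU) + v).
    """
    overlap = iou(pred, gt)
    cpx, cpy = pred.center
    cgx, cgy = gt.center
    rho2 = (cpx - cgx) ** 2 + (cpy - cgy) ** 2
    cw = max(pred.x2, gt.x2) - min(pred.x1, gt.x1)
    ch = max(pred.y2, gt.y2) - min(pred.y1, gt.y1)
    c2 = cw**2 + ch**2
    d = math.atan(gt.width / gt.height) - math.atan(pred.width / pred.height)
    if variant == "improved":
        return (
            1.0
            - overlap
            + rho2 / c2
            + (4.0 / math.pi**2) * d**4 * (1.0 - overlap)
            + (4.0 / math.pi**2) * d**2
        )
    if variant == "ciou":
        v = (4.0 / math.pi**2) * d**2
        alpha = v / ((1.0 - overlap) + v) if v > 0.0 else 0.0
        return 1.0 - overlap + rho2 / c2 + alpha * v
    raise ValueError(f"unknown variant {variant!r}")


def nms(boxes: list[BBox], iou_threshold: float) -> list[BBox]:
    """Greedy non-maximum suppression.

    Boxes are visited in descending score order (ties broken by original
    index); a box is dropped iff its IoU with an already-retained box
    exceeds ``iou_threshold``.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie strictly between 0 and 1")
    if any(b.score is None for b in boxes):
        raise ValueError("all boxes need a score for NMS")
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].score, i))
    kept: list[int] = []
    for i in order:
        if all(iou(boxes[i], boxes[j]) <= iou_threshold for j in kept):
            kept.append(i)
    kept.sort()
    return [boxes[i] for i in kept]
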