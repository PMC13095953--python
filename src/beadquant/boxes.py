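"""Half-open pixel rectangles and the overlap geometry built on them.

A box is ``(x0, y0, x1, y1)`` with ``x0 <= x < x1`` and ``y0 <= y < y1``
(origin top-left, y down).  All detection matching and non-maximum
suppression in this package reduce to :func:`iou` on such boxes.
"""

from __future__ import annotations

import math

from .errors import ValidationError

Box = tuple[float, float, float, float]


def box_area(box: Box) -> float:
    x0, y0, x1, y1 = box
    return max(0.0, x1 - x0) * max(0.0, y1 - y0)


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection-over-union of two half-open boxes; 0 when disjoint.

    Raises :class:`ValidationError` on zero-area boxes, for which the ratio
    is undefined.
    """
    area_a = box_area(box_a)
    area_b = box_area(box_b)
    if area_a <= 0 or area_b <= 0:
        raise ValidationError("iou is undefined for zero-area boxes")
    ix0 = max(box_a[0], box_b[0])
    iy0 = max(box_a[1], box_b[1])
    ix1 = min(box_a[2], box_b[2])
    iy1 = min(box_a[3], box_b[3])
    inter = max(0.0, ix1 - ix0) * max(0.0, iy1 - iy0)
    if inter == 0.0:
        return 0.0
    return inter / (area_a + area_b - inter)


def circle_bbox(cx: float, cy: float, radius: float) -> tuple[int, int, int, int]:
    """Smallest integer half-open pixel box enclosing the circle."""
    return (
        int(math.floor(cx - radius)),
        int(math.floor(cy - radius)),
        int(math.ceil(cx + radius)),
        int(math.ceil(cy + radius)),
    )
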