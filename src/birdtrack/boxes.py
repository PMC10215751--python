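"""Axis-aligned bounding boxes and the power-generalized IoU loss family.

Boxes live in image coordinates: origin at the top-left corner, x grows
rightward, y grows downward, units are pixels (continuous reals).  A box is
corner-encoded as ``(x_min, y_min, x_max, y_max)``; conversions to and from
``(x, y, w, h)`` (top-left + size) and ``(cx, cy, w, h)`` (center + size) are
provided because detector outputs and tracker state use those encodings.

The loss family generalizes the classic IoU, GIoU and DIoU regression losses
by raising the IoU term and the penalty term to a power ``alpha``:

    L_a-IoU  = 1 - IoU**a
    L_a-GIoU = 1 - IoU**a + (|C \\ (A u B)| / |C|)**a
    L_a-DIoU = 1 - IoU**a + (rho^2 / c^2)**a

where ``C`` is the smallest enclosing box of the pair, ``rho`` the Euclidean
distance between box centers and ``c`` the diagonal of ``C``.  With
``alpha=1`` each reduces exactly to its classic counterpart.  ``alpha`` above
one up-weights high-IoU pairs, which sharpens bounding-box regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BBox",
    "LossConfig",
    "iou",
    "intersection_area",
    "enclosing_box",
    "alpha_loss",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, corner-encoded, with non-negative extent."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v) for v in (self.x_min, self.y_min, self.x_max, self.y_max)
        ):
            raise ValueError("box coordinates must be finite")
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    # --- encodings -------------------------------------------------------
    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "BBox":
        """Top-left corner plus width/height."""
        return cls(x, y, x + w, y + h)

    @classmethod
    def from_cxcywh(cls, cx: float, cy: float, w: float, h: float) -> "BBox":
        """Center plus width/height."""
        return cls(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)

    def to_xywh(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.width, self.height)

    def to_cxcywh(self) -> tuple[float, float, float, float]:
        cx, cy = self.center
        return (cx, cy, self.width, self.height)

    def clip(self, width: float, height: float) -> "BBox":
        """Clip to the image rectangle [0, width] x [0, height]."""
        x0 = min(max(self.x_min, 0.0), width)
        y0 = min(max(self.y_min, 0.0), height)
        x1 = min(max(self.x_max, 0.0), width)
        y1 = min(max(self.y_max, 0.0), height)
        return BBox(x0, y0, x1, y1)

    def intersects(self, other: "BBox") -> bool:
        """Positive-area overlap (boundary contact does not count)."""
        return intersection_area(self, other) > 0.0


def intersection_area(a: BBox, b: BBox) -> float:
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0.0 or h <= 0.0:
        return 0.0
    return w * h


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union, in [0, 1].

    Two zero-area boxes have IoU 0 by convention (robustness to collapsed
    predictions); identical positive-area boxes have IoU 1.
    """
    inter = intersection_area(a, b)
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def enclosing_box(a: BBox, b: BBox) -> BBox:
    """Smallest axis-aligned box containing both inputs."""
    return BBox(
        min(a.x_min, b.x_min),
        min(a.y_min, b.y_min),
        max(a.x_max, b.x_max),
        max(a.y_max, b.y_max),
    )


_VARIANTS = ("iou", "giou", "diou")


@dataclass(frozen=True)
class LossConfig:
    """Power exponent and base-loss variant for :func:`alpha_loss`.

    ``alpha=3`` is the value recommended in the power-IoU-loss literature and
    the package default; ``alpha=1`` recovers the classic losses.
    """

    alpha: float = 3.0
    variant: str = "iou"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and positive, got {self.alpha}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")


def alpha_loss(a: BBox, b: BBox, cfg: LossConfig = LossConfig()) -> float:
    """Power-generalized IoU-family regression loss between two boxes.

    Always finite; exactly 0 for identical positive-area boxes under every
    variant and alpha.  Degenerate (zero-area) boxes take IoU = 0 and a zero
    penalty term where its denominator would vanish.
    """
    al = cfg.alpha
    overlap = iou(a, b)
    loss = 1.0 - overlap**al
    if cfg.variant == "iou":
        return loss
    c = enclosing_box(a, b)
    if cfg.variant == "giou":
        if c.area <= 0.0:
            return loss
        inter = intersection_area(a, b)
        union = a.area + b.area - inter
        return loss + ((c.area - union) / c.area) ** al
    # diou
    c2 = c.width**2 + c.height**2
    if c2 <= 0.0:
        return loss
    (ax, ay), (bx, by) = a.center, b.center
    rho2 = (ax - bx) ** 2 + (ay - by) ** 2
    return loss + (rho2 / c2) ** al
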