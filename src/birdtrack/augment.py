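"""Detector-training data augmentation: mosaic stitching, mixup, HSV jitter.

All three operate on :class:`LabeledImage` (uint8 RGB pixels plus box labels
in pixel coordinates) and are deterministic under an explicit seed or RNG.
When the three are composed, the order used here is mosaic -> mixup -> HSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import color as skcolor

from .boxes import BBox

__all__ = ["LabeledImage", "HsvGains", "mixup", "mosaic", "hsv_jitter"]


@dataclass
class LabeledImage:
    """H x W x 3 uint8 RGB image with (class_id, box) labels in pixels.

    Per-label soft weights in (0, 1] arise from mixup blending and default
    to 1.
    """

    pixels: np.ndarray
    labels: list[tuple[int, BBox]] = field(default_factory=list)
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8 in [0, 255]")
        if self.weights is None:
            self.weights = [1.0] * len(self.labels)
        if len(self.weights) != len(self.labels):
            raise ValueError("one weight per label required")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def copy(self) -> "LabeledImage":
        return LabeledImage(self.pixels.copy(), list(self.labels), list(self.weights))

    @classmethod
    def open(cls, path, labels=None) -> "LabeledImage":
        arr = np.asarray(Image.open(path).convert("RGB"))
        return cls(arr, list(labels) if labels else [])

    def save(self, path) -> None:
        Image.fromarray(self.pixels).save(path)


@dataclass(frozen=True)
class HsvGains:
    """Maximum fractional multiplicative jitter per HSV channel.

    Defaults are standard detector-training values; a gain of 0 disables
    that channel's jitter.  Hue is documented in degrees [0, 360) and wraps;
    saturation and value clip to their valid range.
    """

    h_gain: float = 0.015
    s_gain: float = 0.7
    v_gain: float = 0.4

    def __post_init__(self) -> None:
        for g in (self.h_gain, self.s_gain, self.v_gain):
            if not (math.isfinite(g) and g >= 0):
                raise ValueError("gains must be finite and non-negative")


def mixup(a: LabeledImage, b: LabeledImage, lam: float) -> LabeledImage:
    """Convex blend of two images and their label sets.

    ``pixels = lam*a + (1-lam)*b`` (rounded, clipped to [0, 255]); the output
    carries a's labels at weight ``lam`` and b's at ``1-lam`` (zero-weight
    labels are dropped, so ``lam=1`` returns a exactly).  Callers typically
    draw ``lam ~ Beta(beta, beta)`` with beta = 8.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(
            f"image shapes differ: {a.pixels.shape} vs {b.pixels.shape}"
        )
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    mixed = np.clip(
        np.rint(lam * a.pixels.astype(float) + (1.0 - lam) * b.pixels.astype(float)),
        0,
        255,
    ).astype(np.uint8)
    labels: list[tuple[int, BBox]] = []
    weights: list[float] = []
    for img, w in ((a, lam), (b, 1.0 - lam)):
        if w <= 0.0:
            continue
        labels.extend(img.labels)
        weights.extend(w * wi for wi in img.weights)
    return LabeledImage(mixed, labels, weights)


def draw_beta_lambda(rng: np.random.Generator, beta: float = 8.0) -> float:
    """Mixing coefficient lam ~ Beta(beta, beta)."""
    return float(rng.beta(beta, beta))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def mosaic(
    samples: list[LabeledImage],
    out_size: tuple[int, int],
    center: tuple[float, float] | None = None,
    seed=0,
    margin: float = 0.25,
    min_area_px: float = 4.0,
    min_area_frac: float = 0.1,
) -> LabeledImage:
    """Stitch four labeled images into one canvas split at a center point.

    Each sample is scaled (aspect-preserving, to cover its quadrant) and
    anchored at the center point; the overhang is cropped at the canvas edge.
    Label boxes follow the same scale + offset, are clipped to the canvas,
    and a clipped box is dropped when its area falls below
    ``max(min_area_px, min_area_frac * scaled original area)``.

    ``center`` is ``(cy, cx)``; when omitted it is drawn uniformly inside the
    inner ``margin`` fraction of the canvas under ``seed``.
    """
    if len(samples) != 4:
        raise ValueError(f"mosaic needs exactly 4 samples, got {len(samples)}")
    out_h, out_w = out_size
    if center is None:
        rng = _rng(seed)
        cy = float(rng.uniform(margin * out_h, (1 - margin) * out_h))
        cx = float(rng.uniform(margin * out_w, (1 - margin) * out_w))
    else:
        cy, cx = float(center[0]), float(center[1])
    if not (0 < cy < out_h and 0 < cx < out_w):
        raise ValueError("mosaic center must lie strictly inside the canvas")

    canvas = np.zeros((out_h, out_w, 3), dtype=np.uint8)
    labels: list[tuple[int, BBox]] = []
    weights: list[float] = []
    # quadrant extents (height, width) and the corner of each sample that
    # sits on the center point
    quads = [
        (cy, cx, "br"),  # top-left quadrant
        (cy, out_w - cx, "bl"),  # top-right
        (out_h - cy, cx, "tr"),  # bottom-left
        (out_h - cy, out_w - cx, "tl"),  # bottom-right
    ]
    for sample, (qh, qw, anchor) in zip(samples, quads):
        s = max(qh / sample.height, qw / sample.width)
        rh, rw = max(1, round(sample.height * s)), max(1, round(sample.width * s))
        resized = np.asarray(
            Image.fromarray(sample.pixels).resize((rw, rh), Image.BILINEAR)
        )
        # top-left of the scaled sample on the canvas plane (may be negative)
        ox = cx - rw if anchor in ("br", "tr") else cx
        oy = cy - rh if anchor in ("br", "bl") else cy
        # paste the visible part
        x0, y0 = max(0, math.floor(ox)), max(0, math.floor(oy))
        x1 = min(out_w, math.floor(ox) + rw)
        y1 = min(out_h, math.floor(oy) + rh)
        if x1 > x0 and y1 > y0:
            sx0, sy0 = x0 - math.floor(ox), y0 - math.floor(oy)
            canvas[y0:y1, x0:x1] = resized[sy0 : sy0 + (y1 - y0), sx0 : sx0 + (x1 - x0)]
        # map labels through the same scale + offset
        for (cls_id, box), w in zip(sample.labels, sample.weights):
            mapped_w, mapped_h = box.width * s, box.height * s
            mapped = BBox(
                ox + box.x_min * s,
                oy + box.y_min * s,
                ox + box.x_max * s,
                oy + box.y_max * s,
            )
            clipped = mapped.clip(out_w, out_h)
            if clipped.area < max(min_area_px, min_area_frac * mapped_w * mapped_h):
                continue
            labels.append((cls_id, clipped))
            weights.append(w)
    return LabeledImage(canvas, labels, weights)


def hsv_jitter(img: LabeledImage, gains: HsvGains = HsvGains(), seed=0) -> LabeledImage:
    """Multiplicative hue/saturation/value perturbation.

    Each channel is scaled by ``1 + u*gain`` with ``u ~ Uniform(-1, 1)`` drawn
    once per channel under ``seed``.  Hue wraps around its circle (360 deg,
    stored internally on the unit scale); saturation and value clip to [0, 1].
    Labels pass through untouched.  With all gains 0 the output is the
    RGB -> HSV -> RGB round trip of the input (identity up to rounding).
    """
    rng = _rng(seed)
    u = rng.uniform(-1.0, 1.0, size=3)
    fh = 1.0 + u[0] * gains.h_gain
    fs = 1.0 + u[1] * gains.s_gain
    fv = 1.0 + u[2] * gains.v_gain
    hsv = skcolor.rgb2hsv(img.pixels.astype(float) / 255.0)
    hsv[..., 0] = np.mod(hsv[..., 0] * fh, 1.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * fs, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * fv, 0.0, 1.0)
    rgb = np.clip(np.rint(skcolor.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    return LabeledImage(rgb, list(img.labels), list(img.weights))
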