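"""File formats, dataset splitting and configuration.

Detections and tracks travel in MOT-style CSV: ten comma-separated fields
per line, ``frame, id, x, y, w, h, conf, class, -1, -1`` with ``id = -1``
for raw detections, 0-based pixel coordinates and half-open extents
``[x, x+w) x [y, y+h)``.  Image labels use the YOLO text dialect (one
``class cx cy w h`` line per box, normalized to [0, 1]); the whole-body and
head-only annotation dialects share this format and are distinguished only
by a configuration field.  Appearance embeddings ride in an NPZ sidecar
keyed by frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .boxes import BBox
from .tracker import Detection, TrackRow

__all__ = [
    "MotRecord",
    "SplitSpec",
    "read_mot",
    "write_mot",
    "split_dataset",
    "read_yolo_labels",
    "write_yolo_labels",
    "detections_from_mot",
    "detections_to_mot",
    "track_rows_from_mot",
    "track_rows_to_mot",
    "save_embeddings",
    "load_embeddings",
    "load_config",
]


@dataclass(frozen=True)
class MotRecord:
    frame: int
    id: int
    x: float
    y: float
    w: float
    h: float
    conf: float
    class_id: int
    r1: int = -1
    r2: int = -1

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame must be >= 1, got {self.frame}")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got w={self.w}, h={self.h}")

    def box(self) -> BBox:
        return BBox.from_xywh(self.x, self.y, self.w, self.h)


def _fmt(v: float) -> str:
    # shortest round-trip representation keeps write . read the identity
    return repr(int(v)) if float(v).is_integer() else repr(float(v))


def write_mot(records: list[MotRecord], path) -> None:
    lines = [
        ",".join(
            [
                str(r.frame),
                str(r.id),
                _fmt(r.x),
                _fmt(r.y),
                _fmt(r.w),
                _fmt(r.h),
                _fmt(r.conf),
                str(r.class_id),
                str(r.r1),
                str(r.r2),
            ]
        )
        for r in records
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_mot(path) -> list[MotRecord]:
    records: list[MotRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split(",")
        if len(fields) != 10:
            raise ValueError(
                f"{path}:{lineno}: expected 10 comma-separated fields, got {len(fields)}"
            )
        try:
            records.append(
                MotRecord(
                    frame=int(fields[0]),
                    id=int(fields[1]),
                    x=float(fields[2]),
                    y=float(fields[3]),
                    w=float(fields[4]),
                    h=float(fields[5]),
                    conf=float(fields[6]),
                    class_id=int(fields[7]),
                    r1=int(fields[8]),
                    r2=int(fields[9]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def detections_to_mot(stream: list[list[Detection]]) -> list[MotRecord]:
    """Per-frame detections -> MOT records with id = -1."""
    records = []
    for dets in stream:
        for d in dets:
            x, y, w, h = d.box.to_xywh()
            records.append(MotRecord(d.frame, -1, x, y, w, h, d.confidence, d.class_id))
    return records


def detections_from_mot(
    records: list[MotRecord], embeddings: dict[int, np.ndarray] | None = None
) -> list[list[Detection]]:
    """MOT records -> per-frame detection lists (frame 1 .. max frame).

    ``embeddings`` maps frame -> (n_dets_in_frame, d) array in record order.
    """
    if not records:
        return []
    n_frames = max(r.frame for r in records)
    stream: list[list[Detection]] = [[] for _ in range(n_frames)]
    for r in records:
        app = None
        if embeddings is not None and r.frame in embeddings:
            app = embeddings[r.frame][len(stream[r.frame - 1])]
        stream[r.frame - 1].append(
            Detection(r.frame, r.box(), r.conf, r.class_id, app)
        )
    return stream


def track_rows_to_mot(rows: list[TrackRow]) -> list[MotRecord]:
    records = []
    for r in rows:
        x, y, w, h = r.box.to_xywh()
        records.append(MotRecord(r.frame, r.track_id, x, y, w, h, 1.0, r.species))
    return records


def track_rows_from_mot(records: list[MotRecord]) -> list[TrackRow]:
    return [
        TrackRow(r.frame, r.id, r.box(), r.class_id, "confirmed") for r in records
    ]


# --- YOLO label dialect ---------------------------------------------------


def write_yolo_labels(labels: list[tuple[int, BBox]], path, img_w: int, img_h: int) -> None:
    lines = []
    for cls_id, box in labels:
        cx, cy, w, h = box.to_cxcywh()
        lines.append(
            f"{cls_id} {cx / img_w:.6f} {cy / img_h:.6f} {w / img_w:.6f} {h / img_h:.6f}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_yolo_labels(path, img_w: int, img_h: int) -> list[tuple[int, BBox]]:
    labels: list[tuple[int, BBox]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        cls_id = int(fields[0])
        cx, cy, w, h = (float(f) for f in fields[1:])
        labels.append((cls_id, BBox.from_cxcywh(cx * img_w, cy * img_h, w * img_w, h * img_h)))
    return labels


# --- dataset split --------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test ratios with the floor/floor/remainder size rule."""

    ratios: tuple[float, float, float] = (0.85, 0.10, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {self.ratios}")
        if min(self.ratios) < 0:
            raise ValueError("ratios must be non-negative")


def split_dataset(
    n_items: int, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint shuffled (train, val, test) index partition of range(n_items).

    Sizes are ``floor(N * r_train)``, ``floor(N * r_val)`` and the remainder,
    which reproduces an 85/10/5 split of 3737 items as 3176/373/188.
    """
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    rng = np.random.default_rng(spec.seed)
    idx = rng.permutation(n_items)
    n_train = int(np.floor(n_items * spec.ratios[0]))
    n_val = int(np.floor(n_items * spec.ratios[1]))
    return idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]


# --- embeddings sidecar and config ---------------------------------------


def save_embeddings(stream: list[list[Detection]], path) -> None:
    """NPZ sidecar: key ``f{frame:06d}`` -> (n_dets, d) array in detection
    order; frames whose detections carry no appearance are omitted."""
    arrays = {}
    for dets in stream:
        if dets and all(d.appearance is not None for d in dets):
            arrays[f"f{dets[0].frame:06d}"] = np.stack([d.appearance for d in dets])
    np.savez(path, **arrays)


def load_embeddings(path) -> dict[int, np.ndarray]:
    with np.load(path) as z:
        return {int(k[1:]): z[k] for k in z.files}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
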