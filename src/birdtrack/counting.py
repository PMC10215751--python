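"""Species-wise area counting with a counting board.

The counting board is a 0/1 matrix the size of the image: it starts filled
with 1 and the counting region — a centered rectangle scaled by
``sqrt(coverage)`` per axis, covering ``coverage`` (default 95%) of the image
— is zeroed.  Per frame, each tracked bird's position is written back as 1s
on a working copy of the board; if that puts a 1 inside the counting region
the bird is "in the counting area".  The first time a (species, track ID)
pair is seen inside the region, that species' tally is incremented; the ID
is remembered so later frames never re-count it.  Counts are therefore
monotone non-decreasing and idempotent per frame.

By default a bird's position is its full box footprint (any overlap with the
region counts); ``mode="center"`` tests only the box-center cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil, floor, sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .boxes import BBox

__all__ = [
    "CountingBoard",
    "SpeciesCounter",
    "make_board",
    "mark_and_test",
    "update_counts",
    "run_counting",
]


@dataclass
class CountingBoard:
    """0/1 grid with a zeroed rectangular counting region.

    ``region`` is the half-open cell rectangle (row0, col0, row1, col1).
    """

    grid: np.ndarray
    region: tuple[int, int, int, int]

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    def region_box(self) -> BBox:
        """The counting region as a pixel-coordinate box."""
        r0, c0, r1, c1 = self.region
        return BBox(c0, r0, c1, r1)


def make_board(h: int, w: int, coverage: float = 0.95) -> CountingBoard:
    """Board of size h x w with a centered region covering ``coverage``.

    The region side along each axis is ``round(dim * sqrt(coverage))`` cells,
    so the zeroed fraction equals the requested coverage up to one-cell
    quantization.
    """
    if h < 1 or w < 1:
        raise ValueError("board dimensions must be >= 1")
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    side_h = int(round(h * sqrt(coverage)))
    side_w = int(round(w * sqrt(coverage)))
    r0, c0 = (h - side_h) // 2, (w - side_w) // 2
    grid = np.ones((h, w), dtype=np.int8)
    grid[r0 : r0 + side_h, c0 : c0 + side_w] = 0
    return CountingBoard(grid, (r0, c0, r0 + side_h, c0 + side_w))


def _covered_cells(board: CountingBoard, box: BBox) -> tuple[int, int, int, int] | None:
    """Half-open cell rectangle covered by a pixel box, clipped to the image;
    None when the box lies entirely outside."""
    c0 = max(0, floor(box.x_min))
    r0 = max(0, floor(box.y_min))
    c1 = min(board.width, ceil(box.x_max))
    r1 = min(board.height, ceil(box.y_max))
    if c1 <= c0 or r1 <= r0:
        return None
    return r0, c0, r1, c1


def mark_and_test(board: CountingBoard, box: BBox, mode: str = "box") -> bool:
    """Write the bird's position onto a working copy of the board and report
    whether a 1 now exists inside the counting region.

    Equivalent to intersecting the box's covered cells with the region, so no
    full-grid copy is materialized; the persistent board is untouched (it is
    conceptually reset between frames).  A box entirely outside the image
    yields False.
    """
    if mode == "center":
        cx, cy = box.center
        r0, c0, r1, c1 = board.region
        return (c0 <= cx < c1) and (r0 <= cy < r1)
    if mode != "box":
        raise ValueError(f"mode must be 'box' or 'center', got {mode!r}")
    cells = _covered_cells(board, box)
    if cells is None:
        return False
    r0, c0, r1, c1 = cells
    g0, h0, g1, h1 = board.region
    return r0 < g1 and g0 < r1 and c0 < h1 and h0 < c1


def render_marked(board: CountingBoard, boxes: Iterable[BBox]) -> np.ndarray:
    """Debug view: the board grid with one frame's boxes written back as 1s."""
    grid = board.grid.copy()
    for box in boxes:
        cells = _covered_cells(board, box)
        if cells is not None:
            r0, c0, r1, c1 = cells
            grid[r0:r1, c0:c1] = 1
    return grid


@dataclass
class SpeciesCounter:
    """Per-species sets of counted track IDs; counts = set cardinalities."""

    seen: dict[int, set[int]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[int, int]:
        return {s: len(ids) for s, ids in self.seen.items()}

    @property
    def total(self) -> int:
        return sum(len(ids) for ids in self.seen.values())


def update_counts(
    counter: SpeciesCounter,
    tracked: Sequence[tuple[int, int, BBox]],
    board: CountingBoard,
    mode: str = "box",
) -> SpeciesCounter:
    """Fold one frame of confirmed tracks (track_id, species, box) into the
    counter: first-seen IDs inside the counting region are recorded."""
    for track_id, species, box in tracked:
        if track_id < 0:
            raise ValueError(f"track IDs must be non-negative, got {track_id}")
        if mark_and_test(board, box, mode=mode):
            counter.seen.setdefault(species, set()).add(track_id)
    return counter


def run_counting(
    track_rows: Iterable,
    image_size: tuple[int, int],
    checkpoints: Sequence[int],
    coverage: float = 0.95,
    mode: str = "box",
) -> dict[int, dict[int, int]]:
    """Cumulative per-species counts at each checkpoint frame.

    ``track_rows`` is an iterable of objects with frame, track_id, box and
    species attributes (e.g. tracker output rows), ordered by frame.  Returns
    ``{checkpoint_frame: {species: count}}``; checkpoints beyond the end of
    the stream report the final counts with a warning.
    """
    checkpoints = sorted(checkpoints)
    board = make_board(*image_size, coverage=coverage)
    counter = SpeciesCounter()
    results: dict[int, dict[int, int]] = {}
    pending = list(checkpoints)
    last_frame = 0
    for frame, rows in _group_by_frame(track_rows):
        if frame < last_frame:
            raise ValueError("track stream must be ordered by frame")
        while pending and pending[0] < frame:
            results[pending.pop(0)] = dict(sorted(counter.counts.items()))
        update_counts(counter, [(r.track_id, r.species, r.box) for r in rows], board, mode)
        last_frame = frame
        if pending and pending[0] == frame:
            results[pending.pop(0)] = dict(sorted(counter.counts.items()))
    if pending:
        warnings.warn(
            f"checkpoints {pending} lie beyond the end of the stream "
            f"(last frame {last_frame}); reporting final counts",
            stacklevel=2,
        )
        for cp in pending:
            results[cp] = dict(sorted(counter.counts.items()))
    return results


def _group_by_frame(rows: Iterable):
    current: list = []
    current_frame: int | None = None
    for r in rows:
        if current_frame is None or r.frame == current_frame:
            current_frame = r.frame
            current.append(r)
        else:
            yield current_frame, current
            current_frame, current = r.frame, [r]
    if current_frame is not None:
        yield current_frame, current


def counts_table(
    results: dict[int, dict[int, int]], fps: float | None = None
) -> pd.DataFrame:
    """Tidy (checkpoint, species, count) table; checkpoint in seconds when
    ``fps`` is given, otherwise in frames."""
    species = sorted({s for counts in results.values() for s in counts})
    rows = []
    for cp in sorted(results):
        for s in species:
            rows.append(
                {
                    "checkpoint_s" if fps else "checkpoint_frame": cp / fps if fps else cp,
                    "species": s,
                    "count": results[cp].get(s, 0),
                }
            )
    return pd.DataFrame(rows)
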