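"""Tracking-by-detection with a Kalman filter, appearance association and a
matching cascade.

Each track carries an 8-dimensional constant-velocity state
``(u, v, gamma, h, du, dv, dgamma, dh)`` — box-center x and y, aspect ratio
w/h, box height, and their per-frame velocities — observed through the
4-vector ``(u, v, gamma, h)``.  Per frame the engine

1. predicts every track one step forward (dt = 1 frame),
2. associates detections to confirmed tracks in ascending order of
   ``time_since_update`` (the matching cascade: recently seen tracks get
   first pick, which suppresses identity switches), using the minimum cosine
   distance to the track's appearance gallery as cost and a chi-square
   Mahalanobis gate on the predicted measurement to forbid implausible pairs,
3. matches leftover detections to tentative tracks and just-updated
   confirmed tracks by IoU,
4. applies the lifecycle: a new detection spawns a *tentative* track that is
   *confirmed* after ``n_init`` consecutive matches and *deleted* if it
   misses before that; a confirmed track is deleted once it has gone more
   than ``a_max`` frames without a match (it has left the scene).

Only confirmed tracks matched in the current frame emit output rows; the box
reported is the matched detection's box.  Each track's species label is the
running mode of the classes of its matched detections (ties broken by the
most recently seen class).

Process and measurement noise scale with the state height ``h``, so the
filter adapts to object size without per-scene tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import linalg
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2

from .boxes import BBox, iou

__all__ = [
    "Detection",
    "KalmanState",
    "Track",
    "TrackerConfig",
    "Tracker",
    "TrackRow",
    "kf_initiate",
    "kf_predict",
    "kf_update",
    "gating_distance",
    "appearance_cost",
    "hungarian",
    "matching_cascade",
    "GATING_THRESHOLD_95",
]

logger = logging.getLogger(__name__)

# chi-square 0.95 quantile with 4 degrees of freedom (one per measured
# coordinate); pairs whose squared Mahalanobis distance exceeds it are
# considered implausible
GATING_THRESHOLD_95 = float(chi2.ppf(0.95, df=4))

# noise scale relative to state height (per-frame)
_STD_POS = 1.0 / 20.0
_STD_VEL = 1.0 / 160.0

_F = np.eye(8)
_F[:4, 4:] = np.eye(4)  # constant-velocity transition, dt = 1
_H = np.eye(4, 8)  # observe (u, v, gamma, h)

TENTATIVE = "tentative"
CONFIRMED = "confirmed"
DELETED = "deleted"


@dataclass(frozen=True)
class Detection:
    """One frame's observation of one object."""

    frame: int
    box: BBox
    confidence: float = 1.0
    class_id: int = 0
    appearance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError("frame index must be >= 1")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        if self.appearance is not None:
            a = np.asarray(self.appearance, dtype=float)
            n = np.linalg.norm(a)
            if abs(n - 1.0) > 1e-6:
                raise ValueError(f"appearance vector must be unit-norm, |a| = {n}")
            object.__setattr__(self, "appearance", a)

    def measurement(self) -> np.ndarray:
        cx, cy, w, h = self.box.to_cxcywh()
        if w <= 0 or h <= 0:
            raise ValueError("detection box must have positive width and height")
        return np.array([cx, cy, w / h, h])


@dataclass
class KalmanState:
    """Mean (8,) and symmetric PSD covariance (8, 8) of a track state."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (8,) or self.cov.shape != (8, 8):
            raise ValueError("state is an 8-vector with an 8x8 covariance")
        if np.abs(self.cov - self.cov.T).max() > 1e-8:
            raise ValueError("covariance must be symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)

    def to_box(self) -> BBox:
        u, v, g, h = self.mean[:4]
        return BBox.from_cxcywh(u, v, g * h, h)


def kf_initiate(d: Detection) -> KalmanState:
    """New-track state: measured position, zero velocities, h-scaled spread."""
    z = d.measurement()
    mean = np.zeros(8)
    mean[:4] = z
    h = z[3]
    std = [
        2 * _STD_POS * h,
        2 * _STD_POS * h,
        1e-2,
        2 * _STD_POS * h,
        10 * _STD_VEL * h,
        10 * _STD_VEL * h,
        1e-5,
        10 * _STD_VEL * h,
    ]
    return KalmanState(mean, np.diag(np.square(std)))


def _process_noise(h: float) -> np.ndarray:
    std = [
        _STD_POS * h,
        _STD_POS * h,
        1e-2,
        _STD_POS * h,
        _STD_VEL * h,
        _STD_VEL * h,
        1e-5,
        _STD_VEL * h,
    ]
    return np.diag(np.square(std))


def _measurement_noise(h: float) -> np.ndarray:
    std = [_STD_POS * h, _STD_POS * h, 1e-1, _STD_POS * h]
    return np.diag(np.square(std))


def kf_predict(s: KalmanState, process_noise: np.ndarray | None = None) -> KalmanState:
    """One constant-velocity step; covariance grows by the process noise
    (h-scaled by default)."""
    q = _process_noise(s.mean[3]) if process_noise is None else process_noise
    return KalmanState(_F @ s.mean, _F @ s.cov @ _F.T + q)


def _project(
    s: KalmanState, measurement_noise: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    r = _measurement_noise(s.mean[3]) if measurement_noise is None else measurement_noise
    return _H @ s.mean, _H @ s.cov @ _H.T + r


def kf_update(
    s: KalmanState, z: Sequence[float], measurement_noise: np.ndarray | None = None
) -> KalmanState:
    """Measurement update with z = (u, v, gamma, h); Joseph-form covariance."""
    z = np.asarray(z, dtype=float)
    r = _measurement_noise(s.mean[3]) if measurement_noise is None else measurement_noise
    proj_mean, proj_cov = _project(s, r)
    try:
        chol = linalg.cho_factor(proj_cov, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError("singular innovation covariance") from exc
    gain = linalg.cho_solve(chol, (_H @ s.cov).copy(), check_finite=False).T
    mean = s.mean + gain @ (z - proj_mean)
    ikh = np.eye(8) - gain @ _H
    cov = ikh @ s.cov @ ikh.T + gain @ r @ gain.T
    return KalmanState(mean, 0.5 * (cov + cov.T))


def gating_distance(
    s: KalmanState,
    detections: Sequence,
    measurement_noise: np.ndarray | None = None,
) -> np.ndarray:
    """Squared Mahalanobis distance of each measurement from the predicted
    measurement distribution over (u, v, gamma, h)."""
    if len(detections) == 0:
        return np.zeros(0)
    zs = np.array(
        [
            d.measurement() if isinstance(d, Detection) else np.asarray(d, dtype=float)
            for d in detections
        ]
    )
    proj_mean, proj_cov = _project(s, measurement_noise)
    chol = np.linalg.cholesky(proj_cov)
    diff = zs - proj_mean
    sol = linalg.solve_triangular(
        chol, diff.T, lower=True, check_finite=False, overwrite_b=True
    )
    return np.sum(sol * sol, axis=0)


@dataclass
class Track:
    """Identity-bearing object with Kalman state, lifecycle and appearance
    gallery."""

    track_id: int
    state: KalmanState
    status: str = TENTATIVE
    hits: int = 1
    time_since_update: int = 0
    gallery: list[np.ndarray] = field(default_factory=list)
    # class_id -> (count, frame of most recent observation)
    class_votes: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def species(self) -> int:
        """Modal class of matched detections; ties go to the most recent."""
        if not self.class_votes:
            return -1
        # (count, last frame) sorts mode first, most recent on ties
        return max(self.class_votes.items(), key=lambda kv: kv[1])[0]

    def observe_class(self, class_id: int, frame: int) -> None:
        count = self.class_votes.get(class_id, (0, 0))[0]
        self.class_votes[class_id] = (count + 1, frame)

    def add_appearance(self, vec: np.ndarray, budget: int) -> None:
        self.gallery.append(np.asarray(vec, dtype=float))
        if len(self.gallery) > budget:
            del self.gallery[: len(self.gallery) - budget]

    def predicted_box(self) -> BBox:
        return self.state.to_box()


def appearance_cost(t: Track, d: Detection) -> float:
    """Minimum cosine distance between the detection and the track gallery.

    Falls back to IoU cost (1 - IoU of predicted and detected box) when
    either side lacks appearance information.
    """
    if d.appearance is None or not t.gallery:
        logger.debug(
            "track %d / frame %d: missing appearance, falling back to IoU cost",
            t.track_id,
            d.frame,
        )
        return 1.0 - iou(t.predicted_box(), d.box)
    sims = np.array([float(g @ d.appearance) for g in t.gallery])
    return float(1.0 - sims.max())


def hungarian(
    cost: np.ndarray,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-total-cost assignment; +inf entries mark forbidden pairs.

    Returns (matches, unmatched_rows, unmatched_cols).
    """
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    n_rows, n_cols = cost.shape
    if cost.size == 0:
        return [], list(range(n_rows)), list(range(n_cols))
    finite = np.isfinite(cost)
    big = cost[finite].max() if finite.any() else 0.0
    padded = np.where(finite, cost, abs(big) + 1e6)
    rows, cols = linear_sum_assignment(padded)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if finite[r, c]]
    matched_r = {r for r, _ in matches}
    matched_c = {c for _, c in matches}
    return (
        matches,
        [r for r in range(n_rows) if r not in matched_r],
        [c for c in range(n_cols) if c not in matched_c],
    )


@dataclass(frozen=True)
class TrackerConfig:
    """Association and lifecycle parameters.

    ``n_init``: consecutive matches (including the spawning detection) needed
    to confirm a track.  ``a_max``: frames a confirmed track may go unmatched
    before deletion.  ``gating_threshold``: chi-square quantile for the
    4-DOF Mahalanobis gate.  ``max_appearance_distance``: cosine-distance cap
    in the cascade.  ``iou_fallback_threshold``: IoU-cost cap (1 - IoU) in
    the secondary association stage.
    """

    n_init: int = 3
    a_max: int = 30
    gating_threshold: float = GATING_THRESHOLD_95
    appearance_budget: int = 100
    max_appearance_distance: float = 0.2
    iou_fallback_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.a_max < 1:
            raise ValueError("a_max must be >= 1")


def matching_cascade(
    tracks: Sequence[Track],
    detections: Sequence[Detection],
    cfg: TrackerConfig,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Associate detections to predicted tracks.

    Stage 1 matches confirmed tracks in ascending ``time_since_update`` using
    appearance cost under the Mahalanobis gate; stage 2 matches tentative
    tracks plus just-updated (``time_since_update == 0``) confirmed leftovers
    by IoU cost.  Returns (matches, unmatched_track_idx, unmatched_det_idx)
    with indices into the input sequences.
    """
    matches: list[tuple[int, int]] = []
    free_dets = list(range(len(detections)))
    confirmed = [i for i, t in enumerate(tracks) if t.status == CONFIRMED]
    unmatched_confirmed = set(confirmed)

    for age in sorted({tracks[i].time_since_update for i in confirmed}):
        if not free_dets:
            break
        level = [i for i in confirmed if tracks[i].time_since_update == age]
        cost = np.full((len(level), len(free_dets)), np.inf)
        for r, ti in enumerate(level):
            t = tracks[ti]
            gate = gating_distance(t.state, [detections[j] for j in free_dets])
            for c, dj in enumerate(free_dets):
                if gate[c] > cfg.gating_threshold:
                    continue
                ac = appearance_cost(t, detections[dj])
                if ac <= cfg.max_appearance_distance:
                    cost[r, c] = ac
        level_matches, _, _ = hungarian(cost)
        for r, c in level_matches:
            matches.append((level[r], free_dets[c]))
            unmatched_confirmed.discard(level[r])
        taken = {c for _, c in level_matches}
        free_dets = [d for c, d in enumerate(free_dets) if c not in taken]

    # secondary IoU stage: tentative tracks and confirmed tracks that missed
    # the cascade but were matched in the previous frame
    iou_candidates = [i for i, t in enumerate(tracks) if t.status == TENTATIVE]
    iou_candidates += [i for i in unmatched_confirmed if tracks[i].time_since_update == 0]
    still_unmatched = [i for i in unmatched_confirmed if tracks[i].time_since_update != 0]
    if iou_candidates and free_dets:
        cost = np.full((len(iou_candidates), len(free_dets)), np.inf)
        for r, ti in enumerate(iou_candidates):
            pbox = tracks[ti].predicted_box()
            for c, dj in enumerate(free_dets):
                iou_cost = 1.0 - iou(pbox, detections[dj].box)
                if iou_cost <= cfg.iou_fallback_threshold:
                    cost[r, c] = iou_cost
        stage_matches, ur, uc = hungarian(cost)
        matches.extend((iou_candidates[r], free_dets[c]) for r, c in stage_matches)
        unmatched_tracks = still_unmatched + [iou_candidates[r] for r in ur]
        free_dets = [free_dets[c] for c in uc]
    else:
        unmatched_tracks = still_unmatched + iou_candidates
    return matches, sorted(unmatched_tracks), free_dets


class TrackRow(NamedTuple):
    """One confirmed-track output row for one frame."""

    frame: int
    track_id: int
    box: BBox
    species: int
    status: str


class Tracker:
    """Stateful per-frame tracking engine; feed frames in increasing order."""

    def __init__(self, config: TrackerConfig | None = None) -> None:
        self.config = config or TrackerConfig()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None

    def _spawn(self, d: Detection) -> None:
        t = Track(track_id=self._next_id, state=kf_initiate(d))
        self._next_id += 1
        t.observe_class(d.class_id, d.frame)
        if d.appearance is not None:
            t.add_appearance(d.appearance, self.config.appearance_budget)
        if self.config.n_init <= 1:
            t.status = CONFIRMED
        self.tracks.append(t)

    def step(self, frame: int, detections: Sequence[Detection]) -> list[TrackRow]:
        """Advance one frame: predict, associate, update, apply lifecycle.

        Returns output rows for confirmed tracks matched in this frame.
        """
        if self._last_frame is not None and frame <= self._last_frame:
            raise ValueError(
                f"frames must be strictly increasing (got {frame} after {self._last_frame})"
            )
        for d in detections:
            if d.frame != frame:
                raise ValueError(f"detection frame {d.frame} != step frame {frame}")
        self._last_frame = frame

        for t in self.tracks:
            t.state = kf_predict(t.state)

        matches, unmatched_tracks, unmatched_dets = matching_cascade(
            self.tracks, detections, self.config
        )

        out: list[TrackRow] = []
        for ti, dj in matches:
            t, d = self.tracks[ti], detections[dj]
            t.state = kf_update(t.state, d.measurement())
            t.hits += 1
            t.time_since_update = 0
            t.observe_class(d.class_id, frame)
            if d.appearance is not None:
                t.add_appearance(d.appearance, self.config.appearance_budget)
            if t.status == TENTATIVE and t.hits >= self.config.n_init:
                t.status = CONFIRMED
            if t.status == CONFIRMED:
                out.append(TrackRow(frame, t.track_id, d.box, t.species, t.status))

        for ti in unmatched_tracks:
            t = self.tracks[ti]
            t.time_since_update += 1
            if t.status == TENTATIVE:
                t.status = DELETED
            elif t.time_since_update > self.config.a_max:
                t.status = DELETED

        for dj in unmatched_dets:
            self._spawn(detections[dj])

        self.tracks = [t for t in self.tracks if t.status != DELETED]
        out.sort(key=lambda r: r.track_id)
        return out

    def run(self, frames: Sequence[Sequence[Detection]], start: int = 1) -> list[TrackRow]:
        """Track a whole per-frame detection stream; frame i is ``start + i``."""
        rows: list[TrackRow] = []
        for i, dets in enumerate(frames):
            rows.extend(self.step(start + i, dets))
        return rows
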