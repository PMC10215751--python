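import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birdtrack.boxes import BBox, iou
from birdtrack.tracker import (
    CONFIRMED,
    TENTATIVE,
    Detection,
    KalmanState,
    Track,
    Tracker,
    TrackerConfig,
    appearance_cost,
    gating_distance,
    hungarian,
    kf_initiate,
    kf_predict,
    kf_update,
    matching_cascade,
)

TINY_R = np.eye(4) * 1e-10


def unit(*v):
    a = np.asarray(v, dtype=float)
    return a / np.linalg.norm(a)


def det(frame, cx, cy, w=10.0, h=10.0, app=None, class_id=0):
    return Detection(frame, BBox.from_cxcywh(cx, cy, w, h), 1.0, class_id, app)


def brute_force_assignment(cost):
    """Exhaustive minimum over all maximal feasible matchings (oracle)."""
    n_rows, n_cols = cost.shape
    best = np.inf
    k = min(n_rows, n_cols)
    for rows in itertools.permutations(range(n_rows), k):
        for cols in itertools.permutations(range(n_cols), k):
            pairs = [(r, c) for r, c in zip(rows, cols) if np.isfinite(cost[r, c])]
            total = sum(cost[r, c] for r, c in pairs)
            # prefer more matches, then lower cost (matches hungarian's
            # maximal matching among feasible pairs)
            key = (-len(pairs), total)
            if key < (best if isinstance(best, tuple) else (np.inf, np.inf)):
                best = key
    return best


class TestKalman:
    def test_initiate_center_aspect_height(self):
        s = kf_initiate(Detection(1, BBox(0, 0, 10, 20)))
        assert np.allclose(s.mean, [5, 10, 0.5, 20, 0, 0, 0, 0])
        assert np.allclose(s.cov, s.cov.T)
        assert np.all(np.linalg.eigvalsh(s.cov) >= 0)

    def test_initiate_is_deterministic(self):
        d1, d2 = det(1, 5, 5), det(1, 5, 5)
        a, b = kf_initiate(d1), kf_initiate(d2)
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.cov, b.cov)

    def test_initiate_rejects_degenerate_box(self):
        with pytest.raises(ValueError):
            kf_initiate(Detection(1, BBox(0, 0, 0, 5)))

    def test_predict_moves_by_velocity(self):
        s = kf_initiate(det(1, 5, 10, 10, 20))
        s.mean[4:6] = [1.0, 2.0]
        p = kf_predict(s)
        assert np.allclose(p.mean[:4], [6, 12, 0.5, 20])

    def test_predict_zero_velocity_keeps_position_and_grows_covariance(self):
        s = kf_initiate(det(1, 5, 10))
        p = kf_predict(s)
        assert np.allclose(p.mean[:4], s.mean[:4])
        assert np.trace(p.cov) > np.trace(s.cov)

    def test_update_with_predicted_mean_is_noop_on_position(self):
        s = kf_predict(kf_initiate(det(1, 5, 10)))
        u = kf_update(s, s.mean[:4])
        assert np.allclose(u.mean[:4], s.mean[:4], atol=1e-10)
        assert np.trace(u.cov) < np.trace(s.cov)

    def test_update_with_tiny_noise_pins_measurement(self):
        s = kf_predict(kf_initiate(det(1, 5, 10)))
        u = kf_update(s, [7, 7, 1, 10], measurement_noise=TINY_R)
        assert np.allclose(u.mean[:4], [7, 7, 1, 10], atol=1e-3)

    def test_constant_velocity_convergence(self):
        """Noise-free constant-velocity target under a noise-free model:
        position and velocity are fully observable after two updates, so the
        one-step prediction becomes exact."""
        tiny_q = np.eye(8) * 1e-12
        s = kf_initiate(det(1, 10, 10))
        for k in range(1, 8):
            s = kf_predict(s, process_noise=tiny_q)
            z = [10 + 3 * k, 10 + 2 * k, 1.0, 10.0]
            if k >= 5:
                assert np.allclose(s.mean[:2], z[:2], atol=1e-6)
            s = kf_update(s, z, measurement_noise=TINY_R)

    def test_gating_zero_at_predicted_mean_and_monotone(self):
        s = kf_predict(kf_initiate(det(1, 50, 50)))
        z0 = s.mean[:4]
        offsets = [z0 + np.array([dx, 0, 0, 0]) for dx in (0, 1, 2, 5, 10)]
        d = gating_distance(s, offsets)
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(d) > 0)

    def test_gating_matches_explicit_matrix_algebra(self):
        s = kf_predict(kf_initiate(det(1, 50, 50)))
        z = s.mean[:4] + np.array([1.0, -2.0, 0.01, 3.0])
        proj_cov = s.cov[:4, :4] + np.diag(
            np.square([10 / 20, 10 / 20, 1e-1, 10 / 20])
        )
        expected = (z - s.mean[:4]) @ np.linalg.solve(proj_cov, z - s.mean[:4])
        assert gating_distance(s, [z])[0] == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=25), st.integers(0, 10_000))
    def test_covariance_stays_symmetric_psd(self, ops, seed):
        """Arbitrary predict/update sequences keep the covariance valid."""
        rng = np.random.default_rng(seed)
        s = kf_initiate(det(1, 50, 50, 20, 20))
        for do_update in ops:
            s = kf_predict(s)
            if do_update:
                z = s.mean[:4] + rng.normal(0, 1, 4) * [1, 1, 0.01, 1]
                z[2:] = np.maximum(z[2:], 0.01)
                s = kf_update(s, z)
            assert np.allclose(s.cov, s.cov.T, atol=1e-8)
            assert np.min(np.linalg.eigvalsh(s.cov)) >= -1e-9


class TestAssociation:
    def test_appearance_cost_extremes(self):
        t = Track(1, kf_initiate(det(1, 5, 5)), gallery=[unit(1, 0)])
        assert appearance_cost(t, det(2, 5, 5, app=unit(1, 0))) == pytest.approx(0.0)
        assert appearance_cost(t, det(2, 5, 5, app=unit(0, 1))) == pytest.approx(1.0)

    def test_appearance_cost_minimum_over_gallery(self):
        t = Track(1, kf_initiate(det(1, 5, 5)), gallery=[unit(1, 0), unit(0, 1)])
        d = det(2, 5, 5, app=unit(1, 1))
        assert appearance_cost(t, d) == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-9)

    def test_appearance_cost_falls_back_to_iou(self):
        t = Track(1, kf_initiate(det(1, 5, 5)))
        d = det(2, 5, 5)  # same box, no appearance on either side
        assert appearance_cost(t, d) == pytest.approx(0.0, abs=1e-9)

    def test_hungarian_simple_cases(self):
        matches, ur, uc = hungarian(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert sorted(matches) == [(0, 0), (1, 1)] and not ur and not uc
        matches, _, _ = hungarian(np.zeros((3, 3)) + np.eye(3) * 0 + 1 - np.eye(3))
        assert sorted(matches) == [(0, 0), (1, 1), (2, 2)]

    def test_hungarian_respects_forbidden_pairs(self):
        cost = np.array([[np.inf, 1.0], [np.inf, np.inf]])
        matches, ur, uc = hungarian(cost)
        assert matches == [(0, 1)] and ur == [1] and uc == [0]

    def test_hungarian_matches_brute_force_total(self, rng):
        for _ in range(30):
            n, m = rng.integers(1, 6, size=2)
            cost = rng.integers(0, 20, size=(n, m)).astype(float)
            matches, _, _ = hungarian(cost)
            total = sum(cost[r, c] for r, c in matches)
            best = brute_force_assignment(cost)
            assert (-len(matches), total) == pytest.approx(best)

    def _confirmed_track(self, track_id, cx, cy, app, tsu=0):
        t = Track(track_id, kf_predict(kf_initiate(det(1, cx, cy))), status=CONFIRMED,
                  gallery=[app], time_since_update=tsu)
        return t

    def test_cascade_matches_nearby_detection(self):
        t = self._confirmed_track(1, 50, 50, unit(1, 0))
        dets = [det(2, 51, 50, app=unit(1, 0))]
        matches, ut, ud = matching_cascade([t], dets, TrackerConfig())
        assert matches == [(0, 0)] and not ut and not ud

    def test_gate_dominates_appearance(self):
        """A detection far outside the Mahalanobis gate stays unmatched even
        with a perfect appearance match (and fails the IoU stage too)."""
        t = self._confirmed_track(1, 50, 50, unit(1, 0))
        dets = [det(2, 500, 500, app=unit(1, 0))]
        matches, ut, ud = matching_cascade([t], dets, TrackerConfig())
        assert not matches and ut == [0] and ud == [0]

    def test_cascade_prefers_recently_updated_track(self):
        app = unit(1, 0)
        fresh = self._confirmed_track(1, 50, 50, app, tsu=0)
        stale = self._confirmed_track(2, 50, 50, app, tsu=5)
        dets = [det(2, 50, 50, app=app)]
        matches, ut, _ = matching_cascade([stale, fresh], dets, TrackerConfig())
        assert matches == [(1, 0)]
        assert ut == [0]


class TestLifecycle:
    def test_confirmation_at_third_consecutive_frame(self):
        tracker = Tracker(TrackerConfig(n_init=3))
        out1 = tracker.step(1, [det(1, 50, 50, app=unit(1, 0))])
        out2 = tracker.step(2, [det(2, 51, 50, app=unit(1, 0))])
        out3 = tracker.step(3, [det(3, 52, 50, app=unit(1, 0))])
        assert out1 == [] and out2 == []
        assert len(out3) == 1 and out3[0].status == CONFIRMED and out3[0].frame == 3

    def test_tentative_track_deleted_on_first_miss(self):
        tracker = Tracker(TrackerConfig())
        tracker.step(1, [det(1, 50, 50, app=unit(1, 0))])
        tracker.step(2, [])
        assert tracker.tracks == []

    def test_confirmed_track_survives_a_max_misses_then_dies(self):
        a_max = 5
        tracker = Tracker(TrackerConfig(a_max=a_max))
        for f in range(1, 4):
            tracker.step(f, [det(f, 50 + f, 50, app=unit(1, 0))])
        assert tracker.tracks[0].status == CONFIRMED
        for f in range(4, 4 + a_max):
            tracker.step(f, [])
            assert len(tracker.tracks) == 1
        tracker.step(4 + a_max, [])
        assert tracker.tracks == []

    def test_out_of_order_frames_rejected(self):
        tracker = Tracker()
        tracker.step(2, [])
        with pytest.raises(ValueError):
            tracker.step(2, [])

    def test_species_is_mode_of_matched_classes(self):
        tracker = Tracker(TrackerConfig(n_init=1))
        app = unit(1, 0)
        classes = [3, 3, 5, 3, 5]
        rows = []
        for f, c in enumerate(classes, start=1):
            rows += tracker.step(f, [det(f, 50 + f, 50, app=app, class_id=c)])
        assert rows[-1].species == 3  # 3 observed thrice, 5 twice

    def test_two_separated_objects_no_id_switches(self):
        """Two noise-free constant-velocity birds far apart: exactly two IDs,
        each with a consistent box history matching its own trajectory."""
        tracker = Tracker()
        apps = [unit(1, 0, 0), unit(0, 1, 0)]
        rows = []
        for f in range(1, 51):
            d1 = det(f, 30 + 2 * f, 100, app=apps[0], class_id=0)
            d2 = det(f, 400 - 2 * f, 300, app=apps[1], class_id=1)
            rows += tracker.step(f, [d1, d2])
        ids = {r.track_id for r in rows}
        assert len(ids) == 2
        by_id = {i: [r for r in rows if r.track_id == i] for i in ids}
        for i, rs in by_id.items():
            species = {r.species for r in rs}
            assert len(species) == 1  # no identity ever swapped classes
            for r in rs:
                truth_cx = 30 + 2 * r.frame if r.species == 0 else 400 - 2 * r.frame
                truth_cy = 100 if r.species == 0 else 300
                truth = BBox.from_cxcywh(truth_cx, truth_cy, 10, 10)
                assert iou(r.box, truth) > 0.99

    def test_determinism_identical_streams(self):
        def run():
            tracker = Tracker()
            rng = np.random.default_rng(3)
            rows = []
            for f in range(1, 30):
                dets = [
                    det(f, 50 + 2 * f + rng.normal(0, 0.2), 60, app=unit(1, 0.01 * f)),
                    det(f, 200, 200 + f, app=unit(0, 1)),
                ]
                rows += tracker.step(f, dets)
            return rows

        assert run() == run()
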