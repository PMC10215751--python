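import numpy as np
import pytest

from birdtrack.boxes import BBox
from birdtrack.metrics import (
    ConfusionCounts,
    PRCurve,
    average_precision,
    build_pr_curve,
    evaluate_detections,
    match_to_gt,
    mean_average_precision,
    precision_recall_f1_accuracy,
)
from birdtrack.tracker import Detection


def det(cx, cy, conf=1.0, cls=0, frame=1, w=10.0, h=10.0):
    return Detection(frame, BBox.from_cxcywh(cx, cy, w, h), conf, cls)


def ap_oracle(tp_flags, n_gt):
    """Independent step-function integration of the precision envelope.

    For every interval between consecutive distinct recall values, the
    envelope height is found by an O(n^2) scan for the maximum precision at
    recall >= the interval's right edge.
    """
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(~np.asarray(tp_flags, dtype=bool))
    rec = tp / n_gt
    prec = tp / (tp + fp)
    total = 0.0
    prev_r = 0.0
    for r in sorted(set(rec)):
        height = max((p for p, rr in zip(prec, rec) if rr >= r), default=0.0)
        total += (r - prev_r) * height
        prev_r = r
    return total


class TestMatchToGt:
    def test_perfect_detections_all_tp(self):
        gts = [det(20, 20), det(50, 50)]
        dets = [det(20, 20, 0.9), det(50, 50, 0.8)]
        flags, fn = match_to_gt(dets, gts, 0.5)
        assert flags == [True, True] and fn == 0

    def test_low_iou_is_fp_and_fn(self):
        gts = [det(20, 20)]
        dets = [det(26, 20, 0.9)]  # IoU = 4/16 = 0.25 < 0.5
        flags, fn = match_to_gt(dets, gts, 0.5)
        assert flags == [False] and fn == 1

    def test_greedy_confidence_priority_on_shared_gt(self):
        """The higher-confidence detection claims the ground truth even when
        a lower-confidence one overlaps it better."""
        gts = [det(20, 20)]
        d_hi = det(22, 20, 0.9)  # IoU 0.667
        d_lo = det(21, 20, 0.8)  # IoU 0.818
        flags, fn = match_to_gt([d_hi, d_lo], gts, 0.5)
        assert flags == [True, False] and fn == 0

    def test_class_and_frame_are_respected(self):
        gts = [det(20, 20, cls=1, frame=1)]
        wrong_class = det(20, 20, 0.9, cls=0, frame=1)
        wrong_frame = det(20, 20, 0.9, cls=1, frame=2)
        flags, fn = match_to_gt([wrong_class, wrong_frame], gts, 0.5)
        assert flags == [False, False] and fn == 1


class TestConfusionFormulas:
    def test_perfect_counts(self):
        p, r, f1, acc = precision_recall_f1_accuracy(ConfusionCounts(tp=5))
        assert (p, r, f1, acc) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_built_table(self):
        p, r, f1, acc = precision_recall_f1_accuracy(
            ConfusionCounts(tp=3, fp=1, fn=2, tn=0)
        )
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(0.6)
        assert f1 == pytest.approx(2 / 3)
        assert acc == pytest.approx(0.5)

    def test_empty_denominators_yield_zero(self):
        assert precision_recall_f1_accuracy(ConfusionCounts()) == (0, 0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestAveragePrecision:
    def test_single_gt_single_correct_det(self):
        gts = [det(20, 20)]
        curve = build_pr_curve([det(20, 20, 0.9)], gts, class_id=0)
        assert average_precision(curve) == pytest.approx(1.0)

    def test_two_gt_one_correct_det_is_half(self):
        gts = [det(20, 20), det(60, 60)]
        curve = build_pr_curve([det(20, 20, 0.9)], gts, class_id=0)
        assert average_precision(curve) == pytest.approx(0.5)

    def test_matches_independent_integration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            n_gt = int(rng.integers(1, 20))
            flags = rng.uniform(size=n) < 0.5
            flags[: min(n, n_gt)] &= True  # arbitrary pattern; cap TP count
            flags = np.asarray(flags)
            if flags.sum() > n_gt:
                extra = np.flatnonzero(flags)[n_gt:]
                flags[extra] = False
            curve = PRCurve(np.linspace(1, 0.5, n), flags, n_gt)
            assert average_precision(curve) == pytest.approx(
                ap_oracle(flags, n_gt), abs=1e-12
            )

    def test_trailing_false_positive_never_increases_ap(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 15))
            n_gt = int(rng.integers(1, 10))
            flags = rng.uniform(size=n) < 0.5
            if flags.sum() > n_gt:
                flags[np.flatnonzero(flags)[n_gt:]] = False
            conf = np.linspace(1, 0.6, n)
            base = average_precision(PRCurve(conf, flags, n_gt))
            worse = average_precision(
                PRCurve(np.append(conf, 0.1), np.append(flags, False), n_gt)
            )
            assert worse <= base + 1e-12

    def test_undefined_without_ground_truth(self):
        with pytest.raises(ValueError):
            average_precision(PRCurve(np.array([0.9]), np.array([False]), 0))

    def test_duplicate_confidences_use_stable_input_order(self):
        gts = [det(20, 20)]
        dets = [det(40, 40, 0.9), det(20, 20, 0.9)]  # FP listed first, same conf
        curve = build_pr_curve(dets, gts, class_id=0)
        assert curve.tp_flags.tolist() == [False, True]


class TestMeanAveragePrecision:
    def test_all_ones(self):
        assert mean_average_precision({0: 1.0, 1: 1.0, 2: 1.0}) == 1.0

    def test_mean_of_two(self):
        assert mean_average_precision({0: 1.0, 1: 0.5}) == pytest.approx(0.75)

    def test_undefined_classes_excluded(self):
        assert mean_average_precision({0: 0.8, 1: None}) == pytest.approx(0.8)

    def test_error_when_nothing_defined(self):
        with pytest.raises(ValueError):
            mean_average_precision({0: None})


def test_evaluate_detections_perfect_is_all_ones():
    gts = [det(20, 20, cls=c, frame=f) for c in (0, 1) for f in (1, 2)]
    dets = list(gts)
    table = evaluate_detections(dets, gts)
    per_class = table[table["class"] != "all"]
    for col in ("precision", "recall", "f1", "ap@0.5", "ap@0.5:0.95"):
        assert np.allclose(per_class[col].astype(float), 1.0)


def test_evaluate_detections_mean_row(rng):
    gts = [det(20, 20, cls=0), det(60, 60, cls=1)]
    dets = [det(20, 20, 0.9, cls=0), det(62, 60, 0.8, cls=1), det(90, 90, 0.7, cls=1)]
    table = evaluate_detections(dets, gts)
    per_class = table[table["class"] != "all"]
    mean_row = table[table["class"] == "all"].iloc[0]
    assert mean_row["ap@0.5"] == pytest.approx(per_class["ap@0.5"].astype(float).mean())
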