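"""Detection metrics against worked examples and a brute-force PR integral."""

import numpy as np
import pytest

from thermobreath import (
    Annotation,
    AnnotationSet,
    Detection,
    InvalidParameterError,
    UndefinedMetricError,
    average_precision,
    evaluate_detections,
    iou_box,
    iou_mask,
    match_detections,
    oracle_provider,
    precision_recall,
    read_annotations,
    read_detections,
    threshold_detector,
    write_annotations,
    write_detections,
)
from thermobreath.segmentation import mask_bbox


def brute_force_ap(tp_flags, n_gt):
    """Riemann sum over the sorted PR points with explicit envelope search."""
    tp_flags = list(tp_flags)
    points = []
    tp = 0
    for i, flag in enumerate(tp_flags, start=1):
        tp += int(flag)
        points.append((tp / n_gt, tp / i))
    ap, prev_r = 0.0, 0.0
    for i, (r, _) in enumerate(points):
        envelope = max(p for _, p in points[i:])
        ap += (r - prev_r) * envelope
        prev_r = r
    return ap


def _gt(frame_boxes):
    return AnnotationSet(
        frames={
            f: tuple(Annotation(box=b) for b in boxes) for f, boxes in frame_boxes.items()
        }
    )


class TestIou:
    def test_identical_boxes(self):
        assert iou_box((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou_box((0, 0, 5, 5), (10, 10, 15, 15)) == 0.0

    def test_quarter_overlap_counted_in_pixels(self):
        # 5x5 intersection over 100 + 100 - 25 union pixels
        assert iou_box((0, 0, 10, 10), (5, 5, 15, 15)) == pytest.approx(25 / 175)

    def test_symmetric(self, rng):
        for _ in range(20):
            r0, c0 = rng.integers(0, 10, 2)
            a = (int(r0), int(c0), int(r0) + int(rng.integers(1, 10)), int(c0) + int(rng.integers(1, 10)))
            r0, c0 = rng.integers(0, 10, 2)
            b = (int(r0), int(c0), int(r0) + int(rng.integers(1, 10)), int(c0) + int(rng.integers(1, 10)))
            assert iou_box(a, b) == iou_box(b, a)

    def test_degenerate_box_rejected(self):
        with pytest.raises(InvalidParameterError):
            iou_box((0, 0, 0, 10), (0, 0, 5, 5))

    def test_mask_iou_counts_pixels(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        b = np.zeros((6, 6), dtype=np.uint8)
        a[:3, :3] = 1
        b[1:4, 1:4] = 1
        assert iou_mask(a, b) == pytest.approx(4 / 14)


class TestMatching:
    def test_exact_detection_is_tp(self):
        gts = _gt({0: [(0, 0, 10, 10)]})
        dets = [Detection(0, (0, 0, 10, 10), score=0.9)]
        assert match_detections(dets, gts).n_tp == 1

    def test_duplicate_detections_one_to_one(self):
        gts = _gt({0: [(0, 0, 10, 10)]})
        dets = [
            Detection(0, (0, 0, 10, 10), score=0.9),
            Detection(0, (0, 1, 10, 11), score=0.8),
        ]
        result = match_detections(dets, gts)
        assert result.n_tp == 1 and len(result.detections) == 2

    def test_worked_example_two_correct_of_three(self):
        """Five objects, three detections, two accurate: 2 TP and 1 FP."""
        gts = _gt({0: [(0, 0, 10, 10), (20, 0, 30, 10), (40, 0, 50, 10),
                       (60, 0, 70, 10), (80, 0, 90, 10)]})
        dets = [
            Detection(0, (0, 0, 10, 10), score=0.9),    # exact hit
            Detection(0, (20, 1, 30, 11), score=0.8),   # IoU 9/11 > 0.5
            Detection(0, (55, 50, 65, 60), score=0.7),  # far from everything
        ]
        result = match_detections(dets, gts)
        assert result.n_tp == 2
        assert (~result.is_tp).sum() == 1

    def test_iou_exactly_at_threshold_fails_strict_inequality(self):
        gts = _gt({0: [(0, 0, 10, 10)]})
        # overlap 50 of union 100+100-50=150 -> 1/3; vs exact half overlap:
        det_half = Detection(0, (0, 0, 10, 10), score=0.9)
        assert match_detections([det_half], gts, iou_threshold=0.5).n_tp == 1
        # construct IoU exactly 0.5: boxes 10x10 and 10x5 inside it -> 50/100
        det = Detection(0, (0, 0, 10, 5), score=0.9)
        assert iou_box(det.box, (0, 0, 10, 10)) == 0.5
        assert match_detections([det], gts, iou_threshold=0.5).n_tp == 0

    def test_score_permutation_invariant_at_ties(self):
        gts = _gt({0: [(0, 0, 10, 10)], 1: [(0, 0, 10, 10)]})
        dets = [Detection(1, (0, 0, 10, 10), score=0.5), Detection(0, (0, 0, 10, 10), score=0.5)]
        a = match_detections(dets, gts)
        b = match_detections(dets[::-1], gts)
        assert [d.frame_index for d in a.detections] == [d.frame_index for d in b.detections]


class TestPrecisionRecall:
    def test_worked_example_two_thirds_and_two_fifths(self):
        precision, recall = precision_recall(tp=2, n_det=3, n_gt=5)
        assert precision == pytest.approx(2 / 3)
        assert recall == pytest.approx(2 / 5)

    def test_perfect_detector(self):
        assert precision_recall(4, 4, 4) == (1.0, 1.0)

    def test_no_detections_convention(self):
        assert precision_recall(0, 0, 5) == (0.0, 0.0)

    def test_zero_ground_truths_undefined(self):
        with pytest.raises(UndefinedMetricError):
            precision_recall(0, 3, 0)


class TestAveragePrecision:
    def test_single_exact_match_is_one(self):
        gts = _gt({0: [(0, 0, 10, 10)]})
        assert average_precision([Detection(0, (0, 0, 10, 10), score=0.9)], gts) == 1.0

    def test_all_false_positives_is_zero(self):
        gts = _gt({0: [(0, 0, 10, 10)]})
        dets = [Detection(0, (50, 50, 60, 60), score=s) for s in (0.9, 0.5)]
        assert average_precision(dets, gts) == 0.0

    def test_no_ground_truth_is_error(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([], AnnotationSet(frames={}))

    @pytest.mark.parametrize("scores,hits", [
        ((0.9, 0.8, 0.7, 0.6, 0.5), (True, False, True, True, False)),
        ((0.9, 0.8, 0.7, 0.6, 0.5), (False, True, False, True, True)),
        ((0.9, 0.7, 0.5), (True, True, False)),
    ])
    def test_matches_brute_force_pr_integral(self, scores, hits):
        """AP equals the exhaustively computed step-function integral."""
        n_gt = 3
        gt_boxes = [(0, 0, 10, 10), (20, 0, 30, 10), (40, 0, 50, 10)]
        gts = _gt({0: gt_boxes})
        dets = []
        hit_idx = 0
        for score, hit in zip(scores, hits):
            if hit:
                dets.append(Detection(0, gt_boxes[hit_idx], score=score))
                hit_idx += 1
            else:
                dets.append(Detection(0, (70, 70, 80, 80), score=score))
        ap = average_precision(dets, gts)
        assert ap == pytest.approx(brute_force_ap(hits, n_gt))


class TestOracleProvider:
    def test_unperturbed_oracle_is_perfect(self, small_scene):
        dets = oracle_provider(small_scene.gt_masks)
        result = evaluate_detections(dets, small_scene.gt_annotations)
        assert result.precision == result.recall == result.ap == result.map == 1.0

    def test_drop_rate_deterministic_subset(self, small_scene):
        a = oracle_provider(small_scene.gt_masks, drop_rate=0.5, seed=3)
        b = oracle_provider(small_scene.gt_masks, drop_rate=0.5, seed=3)
        assert len(a) == len(b)
        assert all(x.frame_index == y.frame_index and x.box == y.box for x, y in zip(a, b))
        full = oracle_provider(small_scene.gt_masks)
        assert 0 < len(a) < len(full)

    def test_large_dilation_turns_matches_into_fp_and_fn(self, small_scene):
        dets = oracle_provider(small_scene.gt_masks, dilation=8)
        # dilated ellipse vs original: IoU = area ratio, below 0.5 here
        d0 = dets[0]
        gt0 = small_scene.gt_annotations.frames[0][0]
        assert iou_mask(d0.mask, gt0.mask) < 0.5
        result = evaluate_detections(dets, small_scene.gt_annotations, use_mask_iou=True)
        assert result.ap < 1.0


class TestThresholdDetector:
    def test_noise_free_scene_masks_recover_ground_truth(self, small_scene):
        dets = threshold_detector(small_scene.thermal, min_area=10, max_area=500)
        by_frame = {}
        for d in dets:
            by_frame.setdefault(d.frame_index, []).append(d)
        # two nostril components per frame, each overlapping its ground truth
        for i in (0, 10, 25):
            assert len(by_frame[i]) == 2
        gt = small_scene.gt_annotations
        for d in by_frame[0]:
            best = max(iou_mask(d.mask, a.mask) for a in gt.frames[0])
            assert best >= 0.9

    def test_constant_sequence_yields_no_detections(self):
        from thermobreath import ThermalSequence

        seq = ThermalSequence(frames=np.full((2, 10, 10), 25.0), fps=10.0)
        assert threshold_detector(seq, min_area=1, max_area=50) == []

    def test_area_bounds_validated(self, small_scene):
        with pytest.raises(InvalidParameterError):
            threshold_detector(small_scene.thermal, min_area=50, max_area=10)


class TestJsonRoundTrip:
    def test_detections_round_trip(self, tmp_path):
        dets = [
            Detection(0, (0, 0, 10, 10), score=0.9),
            Detection(2, (5, 5, 15, 15), score=0.4),
        ]
        loaded = read_detections(write_detections(dets, tmp_path / "dets.json"))
        assert [(d.frame_index, d.box, d.score) for d in loaded] == [
            (d.frame_index, d.box, d.score) for d in dets
        ]

    def test_annotations_round_trip(self, tmp_path):
        gts = _gt({0: [(0, 0, 10, 10)], 3: [(5, 5, 15, 15), (20, 20, 30, 30)]})
        loaded = read_annotations(write_annotations(gts, tmp_path / "gt.json"))
        assert {f: tuple(a.box for a in objs) for f, objs in loaded.frames.items()} == {
            f: tuple(a.box for a in objs) for f, objs in gts.frames.items()
        }


def test_mask_bbox_is_tight():
    mask = np.zeros((10, 10), dtype=np.uint8)
    mask[2:5, 3:8] = 1
    assert mask_bbox(mask) == (2, 3, 5, 8)
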