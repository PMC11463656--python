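"""Bounding boxes: extraction, merging, matching, NMS, AP, I/O."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from nftseg import (
    BoundingBox,
    assign_boxes_to_tiles,
    average_precision,
    box_iou,
    gt_boxes_from_points,
    masks_to_boxes,
    match_boxes,
    merge_boxes,
    nms,
    object_prf,
    read_detection_file,
    write_detection_file,
)


def _random_box(rng, span=500, max_side=80, confidence=False):
    x0 = rng.uniform(0, span)
    y0 = rng.uniform(0, span)
    return BoundingBox(
        x0, y0, x0 + rng.uniform(5, max_side), y0 + rng.uniform(5, max_side),
        confidence=float(rng.random()) if confidence else None,
    )


class TestMasksToBoxes:
    def test_rectangle_extent_oracle(self):
        m = np.zeros((50, 60), dtype=bool)
        m[7:17, 5:25] = True
        [b] = masks_to_boxes(m)
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (5, 7, 25, 17)

    def test_empty_mask(self):
        assert masks_to_boxes(np.zeros((10, 10), dtype=bool)) == []

    def test_two_disks_two_containing_boxes(self):
        m = np.zeros((200, 200), dtype=bool)
        for cy, cx in [(50, 50), (150, 150)]:
            rr, cc = draw_disk((cy, cx), 20, shape=m.shape)
            m[rr, cc] = True
        boxes = sorted(masks_to_boxes(m), key=lambda b: b.xmin)
        assert len(boxes) == 2
        for b, (cy, cx) in zip(boxes, [(50, 50), (150, 150)]):
            assert b.xmin <= cx - 19 and b.xmax >= cx + 19
            assert b.ymin <= cy - 19 and b.ymax >= cy + 19


class TestMergeBoxes:
    def test_centers_100_apart_merge(self):
        a = BoundingBox(0, 0, 10, 10)
        b = BoundingBox(100, 0, 110, 10)
        [m] = merge_boxes([a, b], center_dist=150)
        assert (m.xmin, m.ymin, m.xmax, m.ymax) == (0, 0, 110, 10)

    def test_centers_200_apart_untouched(self):
        a = BoundingBox(0, 0, 10, 10)
        b = BoundingBox(200, 0, 210, 10)
        assert len(merge_boxes([a, b], center_dist=150)) == 2

    def test_transitive_chain_collapses(self):
        """140-140 chain merges even though the ends are 280 apart."""
        boxes = [BoundingBox(x, 0, x + 10, 10) for x in (0, 140, 280)]
        assert len(merge_boxes(boxes, center_dist=150)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        boxes = [_random_box(rng) for _ in range(12)]
        once = merge_boxes(boxes, center_dist=150)
        twice = merge_boxes(once, center_dist=150)
        assert sorted((b.xmin, b.ymin, b.xmax, b.ymax) for b in once) == sorted(
            (b.xmin, b.ymin, b.xmax, b.ymax) for b in twice
        )

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(10, 10, 10, 20)


class TestGtBoxesFromPoints:
    def test_disk_extent_oracle(self):
        m = np.zeros((600, 600), dtype=bool)
        rr, cc = draw_disk((300, 300), 20, shape=m.shape)
        m[rr, cc] = True
        [b] = gt_boxes_from_points(m, [(300, 300)])
        # skimage disk of radius 20: foreground spans rows/cols 281..319
        rows, cols = np.nonzero(m)
        assert (b.xmin, b.ymin) == (cols.min(), rows.min())
        assert (b.xmax, b.ymax) == (cols.max() + 1, rows.max() + 1)

    def test_blank_window_no_box(self):
        m = np.zeros((600, 600), dtype=bool)
        with pytest.warns(UserWarning):
            assert gt_boxes_from_points(m, [(300, 300)]) == []

    def test_two_points_one_component_two_boxes(self):
        m = np.zeros((600, 1000), dtype=bool)
        m[290:310, 100:900] = True  # long thin component
        boxes = gt_boxes_from_points(m, [(150, 300), (850, 300)])
        assert len(boxes) == 2
        assert boxes[0] != boxes[1]  # windows clip different extents


class TestMatchBoxes:
    def test_identical_sets_all_matched(self, rng):
        boxes = [_random_box(rng) for _ in range(6)]
        res = match_boxes(boxes, list(boxes))
        assert res.tp == 6 and res.fp == 0 and res.fn == 0
        assert all(iou == pytest.approx(1.0) for _, _, iou in res.pairs)

    def test_higher_iou_pred_wins(self):
        gt = [BoundingBox(0, 0, 100, 100)]
        close = BoundingBox(10, 10, 100, 100)
        far = BoundingBox(60, 60, 160, 160)
        res = match_boxes(gt, [far, close])
        assert res.pairs[0][1] == 1  # index of the closer box
        assert res.unmatched_pred == [0]

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_greedy(self, seed):
        rng = np.random.default_rng(seed)
        gt = [_random_box(rng, span=200) for _ in range(5)]
        pred = [_random_box(rng, span=200) for _ in range(5)]
        res = match_boxes(gt, pred, min_iou=0.001)
        # brute force: sort all pairs by IOU desc, greedily accept
        pairs = sorted(
            ((box_iou(g, p), i, j) for i, g in enumerate(gt) for j, p in enumerate(pred)),
            key=lambda t: -t[0],
        )
        used_g, used_p, expected = set(), set(), []
        for iou, i, j in pairs:
            if iou < 0.001 or iou <= 0:
                break
            if i in used_g or j in used_p:
                continue
            expected.append((i, j))
            used_g.add(i)
            used_p.add(j)
        assert sorted((i, j) for i, j, _ in res.pairs) == sorted(expected)

    def test_min_iou_zero_keeps_any_positive_overlap(self):
        gt = [BoundingBox(0, 0, 100, 100)]
        sliver = BoundingBox(99, 99, 300, 300)  # IOU ~ 2e-5
        assert match_boxes(gt, [sliver], min_iou=0.001).tp == 0
        assert match_boxes(gt, [sliver], min_iou=0.0).tp == 1

    def test_sum_rule(self, rng):
        gt = [_random_box(rng) for _ in range(7)]
        pred = [_random_box(rng) for _ in range(4)]
        res = match_boxes(gt, pred)
        assert res.tp + res.fp == len(pred)
        assert res.tp + res.fn == len(gt)

    def test_hungarian_agrees_on_easy_case(self, rng):
        boxes = [_random_box(rng) for _ in range(5)]
        greedy = match_boxes(boxes, list(boxes), method="greedy")
        optimal = match_boxes(boxes, list(boxes), method="hungarian")
        assert sorted(p[:2] for p in greedy.pairs) == sorted(p[:2] for p in optimal.pairs)


class TestObjectPrf:
    def test_counts_case(self):
        res = match_boxes(
            [BoundingBox(i * 100, 0, i * 100 + 10, 10) for i in range(4)],
            [BoundingBox(i * 100, 0, i * 100 + 10, 10) for i in range(3)]
            + [BoundingBox(900, 900, 910, 910)],
        )
        p, r, f1 = object_prf(res)
        assert (p, r, f1) == (0.75, 0.75, 0.75)

    def test_no_predictions_warns(self):
        res = match_boxes([BoundingBox(0, 0, 10, 10)], [])
        with pytest.warns(UserWarning):
            p, r, f1 = object_prf(res)
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_perfect(self, rng):
        boxes = [_random_box(rng) for _ in range(3)]
        assert object_prf(match_boxes(boxes, list(boxes))) == (1.0, 1.0, 1.0)


class TestNms:
    def test_identical_boxes_keep_highest_confidence(self):
        a = BoundingBox(0, 0, 10, 10, confidence=0.9)
        b = BoundingBox(0, 0, 10, 10, confidence=0.8)
        assert nms([a, b]) == [a]

    def test_disjoint_all_kept(self):
        boxes = [BoundingBox(i * 100, 0, i * 100 + 10, 10, confidence=0.5 + 0.1 * i)
                 for i in range(3)]
        assert len(nms(boxes)) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        boxes = [_random_box(rng, span=120, confidence=True) for _ in range(10)]
        expected = []
        pool = sorted(boxes, key=lambda b: -b.confidence)
        while pool:
            best = pool[0]
            expected.append(best)
            pool = [b for b in pool[1:] if box_iou(best, b) <= 0.5]
        assert nms(boxes, iou_thresh=0.5) == expected

    def test_missing_confidence_rejected(self):
        with pytest.raises(ValueError):
            nms([BoundingBox(0, 0, 10, 10)])


class TestAveragePrecision:
    def test_perfect_detector(self, rng):
        gt = {"img": [_random_box(rng) for _ in range(4)]}
        pred = {
            "img": [
                BoundingBox(b.xmin, b.ymin, b.xmax, b.ymax, confidence=0.9)
                for b in gt["img"]
            ]
        }
        ap, _, _ = average_precision(gt, pred, iou_thresh=0.5)
        assert ap == pytest.approx(1.0)

    def test_silent_detector(self, rng):
        gt = {"img": [_random_box(rng)]}
        ap, _, _ = average_precision(gt, {"img": []}, iou_thresh=0.5)
        assert ap == 0.0

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            average_precision({"img": []}, {"img": []})

    def test_toy_staircase_hand_enumeration(self):
        """3 gt, 4 ranked preds (TP, FP, TP, TP): area of the PR staircase."""
        gt = {
            "img": [BoundingBox(0, 0, 10, 10), BoundingBox(100, 0, 110, 10),
                    BoundingBox(200, 0, 210, 10)]
        }
        pred = {
            "img": [
                BoundingBox(0, 0, 10, 10, confidence=0.9),     # TP r=1/3 p=1
                BoundingBox(500, 0, 510, 10, confidence=0.8),  # FP
                BoundingBox(100, 0, 110, 10, confidence=0.7),  # TP r=2/3 p=2/3
                BoundingBox(200, 0, 210, 10, confidence=0.6),  # TP r=1 p=3/4
            ]
        }
        ap, precision, recall = average_precision(gt, pred, iou_thresh=0.5)
        # hand enumeration: envelope is 1 on [0,1/3], 3/4 on (1/3,1]
        expected = (1 / 3) * 1.0 + (2 / 3) * (3 / 4)
        assert ap == pytest.approx(expected)
        assert recall[-1] == pytest.approx(1.0)


class TestAssignBoxesToTiles:
    def test_overhanging_box_clipped_to_center_tile(self):
        b = BoundingBox(1000, 500, 1100, 600)  # center (1050, 550) in tile (1024, 0)
        out = assign_boxes_to_tiles([b], (2048, 2048))
        assert list(out) == [(1024, 0)]
        [clipped] = out[(1024, 0)]
        assert (clipped.xmin, clipped.ymin) == (0, 500)  # xmin clipped at tile edge

    def test_center_on_shared_edge_single_tile(self):
        b = BoundingBox(1014, 0, 1034, 20)  # center x = 1024 exactly
        out = assign_boxes_to_tiles([b], (2048, 2048))
        assert list(out) == [(1024, 0)]

    def test_empty_list(self):
        assert assign_boxes_to_tiles([], (2048, 2048)) == {}

    def test_center_outside_roi_dropped(self):
        b = BoundingBox(3000, 0, 3010, 10)
        with pytest.warns(UserWarning):
            assert assign_boxes_to_tiles([b], (2048, 2048)) == {}


class TestDetectionFiles:
    def test_round_trip(self, tmp_path, rng):
        boxes = [_random_box(rng, confidence=True) for _ in range(5)]
        boxes.append(BoundingBox(1, 2, 3, 4))  # no confidence
        path = write_detection_file(boxes, tmp_path / "det.txt")
        loaded = read_detection_file(path)
        for a, b in zip(loaded, boxes):
            assert (a.xmin, a.ymin, a.xmax, a.ymax) == pytest.approx(
                (b.xmin, b.ymin, b.xmax, b.ymax), abs=1e-4
            )
            assert a.label == b.label

    def test_format_is_label_then_corners(self, tmp_path):
        path = write_detection_file([BoundingBox(1, 2, 3, 4, label=0)],
                                    tmp_path / "d.txt")
        assert path.read_text().split() == ["0", "1", "2", "3", "4"]

    def test_bad_line_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 1 2 3\n")
        with pytest.raises(ValueError):
            read_detection_file(p)


def test_end_to_end_object_f1_on_clean_roi(clean_roi):
    """Classical pipeline boxes vs point-bootstrapped gt boxes: F1 = 1."""
    from nftseg import point_to_mask, stitch_masks

    tiles = []
    for x, y in clean_roi.points:
        tm, crop = point_to_mask(clean_roi.image, (x, y))
        tiles.append((tm, crop.origin))
    pred_mask = stitch_masks(clean_roi.shape, tiles).mask
    pred_boxes = merge_boxes(masks_to_boxes(pred_mask), center_dist=150)

    truth = clean_roi.union_mask(nft_only=True)
    gt_boxes = gt_boxes_from_points(truth, clean_roi.points)
    res = match_boxes(gt_boxes, pred_boxes)
    assert object_prf(res) == (1.0, 1.0, 1.0)
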