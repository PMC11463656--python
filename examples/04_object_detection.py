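"""Object-level evaluation: masks to boxes, merging, greedy matching.

Connected components of the predicted mask become boxes, fragments
within 150 px center-to-center are merged, and predictions are matched
one-to-one against point-bootstrapped ground-truth boxes by descending
IOU (pairs under IOU 0.001 count as false positives).
"""

from nftseg import (
    gt_boxes_from_points,
    make_annotated_roi,
    masks_to_boxes,
    match_boxes,
    merge_boxes,
    object_prf,
    point_to_mask,
    stitch_masks,
)

scene = make_annotated_roi(n_nft=5, dims=(2048, 2048), noise=0.0, seed=21)

tiles = []
for x, y in scene.points:
    tile_mask, crop = point_to_mask(scene.image, (x, y))
    tiles.append((tile_mask, crop.origin))
pred_mask = stitch_masks(scene.shape, tiles).mask

raw_boxes = masks_to_boxes(pred_mask)
pred_boxes = merge_boxes(raw_boxes, center_dist=150)
gt_boxes = gt_boxes_from_points(scene.union_mask(nft_only=True), scene.points)

result = match_boxes(gt_boxes, pred_boxes, min_iou=0.001)
precision, recall, f1 = object_prf(result)

print(f"predicted boxes: {len(raw_boxes)} raw -> {len(pred_boxes)} after merge")
print(f"ground-truth boxes: {len(gt_boxes)}")
for gi, pi, iou in result.pairs:
    print(f"  gt {gi} <-> pred {pi}  IOU {iou:.3f}")
print(f"object precision {precision:.2f}  recall {recall:.2f}  F1 {f1:.2f}")
print(
    "-> on a noise-free scene the classical pipeline recovers every\n"
    "   tangle as exactly one box, so object F1 is 1.0."
)
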