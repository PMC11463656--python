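"""Bootstrap pixel masks from point annotations and check them.

Each nucleolus point becomes a 400x400 tile, the DAB channel is
deconvolved and Otsu-thresholded, and the center-bias (120 px) and
relative-size (50%) filters isolate the annotated tangle.  Tile masks
are stitched into an ROI-level ground-truth mask.
"""

import numpy as np

from nftseg import make_annotated_roi, mask_size_report, point_to_mask, stitch_masks

scene = make_annotated_roi(n_nft=5, dims=(2048, 2048), noise=0.01, seed=7)

tiles = []
for i, (x, y) in enumerate(scene.points):
    tile_mask, crop = point_to_mask(scene.image, (x, y), annotation_id=f"nft_{i}")
    tiles.append((tile_mask, crop.origin))
    truth = scene.masks[i]
    placed = stitch_masks(scene.shape, [(tile_mask, crop.origin)]).mask
    iou = (placed & truth).sum() / (placed | truth).sum()
    print(f"nft_{i}: mask {int(tile_mask.mask.sum()):5d} px, "
          f"blobs kept {tile_mask.retained}, IOU vs truth {iou:.3f}")

roi_mask = stitch_masks(scene.shape, tiles)
print(f"stitched ROI mask foreground: {int(roi_mask.mask.sum())} px")

report = mask_size_report([t for t, _ in tiles])
print(report.to_string(index=False))
print(
    "-> 'fraction' is mask area over the 160,000-px tile; typical tangles\n"
    "   land around 0.05, and empty/oversize rows flag failed bootstraps."
)
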